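"""Structure file I/O and binding-pocket definition.

Reads protein--ligand complexes from PDB, mmCIF, PDBQT (coordinates only)
and SDF files into a light-weight :class:`Complex` model, removing solvent,
ions and hydrogens on the way in.  All coordinates are stored internally in
nanometres; Angstrom values in structure files are converted at this I/O
boundary and nowhere else.

The binding pocket follows the convention used throughout the package: the
set of protein *backbone* heavy atoms whose distance to the geometric centre
of the native ligand's heavy atoms is at most a cutoff (1.0 nm by default,
inclusive boundary).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Complex",
    "PocketSelection",
    "StructureError",
    "StructureParseError",
    "EmptyLigandError",
    "AmbiguousLigandError",
    "EmptyPocketError",
    "read_complex",
    "write_complex",
    "define_pocket",
    "atom_key",
]

ANGSTROM_PER_NM = 10.0

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: Residue names removed during cleaning (waters and common monoatomic ions).
DEFAULT_REMOVE = frozenset(
    {
        "HOH", "WAT", "DOD", "H2O",
        "NA", "K", "CL", "BR", "I", "F",
        "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD", "HG", "LI", "CS", "RB",
    }
)

STANDARD_AA = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


class StructureError(ValueError):
    """Base class for structure I/O problems."""


class StructureParseError(StructureError):
    """The file could not be parsed under the requested dialect."""


class EmptyLigandError(StructureError):
    """No ligand atoms were found after cleaning."""


class AmbiguousLigandError(StructureError):
    """Several ligand copies exist and no selector was given (strict mode)."""


class EmptyPocketError(StructureError):
    """A pocket selection is empty; distance-based metrics must refuse it."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a protein or ligand, coordinates in nm."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    is_backbone: bool
    is_heavy: bool = True

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.is_backbone and self.name not in BACKBONE_NAMES:
            raise StructureError(f"atom {self.name}: backbone flag requires name in N/CA/C/O")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.name)


def atom_key(atom: AtomRecord) -> tuple[str, int, str]:
    """(chain_id, residue_index, atom_name) key used by selections and pairings."""
    return atom.key


@dataclass
class Complex:
    """One protein plus one ligand, heavy atoms only, coordinates in nm."""

    entry_id: str
    ligand_id: str
    protein_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]
    release_date: date | None = None
    source_format: str = "PDB"

    def __post_init__(self) -> None:
        if not self.protein_atoms:
            raise StructureError(f"{self.entry_id}: complex has no protein atoms")
        if not self.ligand_atoms:
            raise EmptyLigandError(f"{self.entry_id}: complex has no ligand atoms")

    def protein_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.protein_atoms])

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.ligand_atoms])

    def backbone_atoms(self) -> list[AtomRecord]:
        return [a for a in self.protein_atoms if a.is_backbone]

    def atom_by_key(self) -> dict[tuple[str, int, str], AtomRecord]:
        return {a.key: a for a in self.protein_atoms + self.ligand_atoms}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Complex":
        """Return a copy with every atom mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def move(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
            return [replace(a, position=R @ a.position + t) for a in atoms]

        return Complex(
            entry_id=self.entry_id,
            ligand_id=self.ligand_id,
            protein_atoms=move(self.protein_atoms),
            ligand_atoms=move(self.ligand_atoms),
            release_date=self.release_date,
            source_format=self.source_format,
        )

    def n_residues(self) -> int:
        return len({(a.chain_id, a.residue_index) for a in self.protein_atoms})

    def has_nonstandard_aa(self) -> bool:
        return any(a.residue_name not in STANDARD_AA for a in self.protein_atoms)


@dataclass(frozen=True)
class PocketSelection:
    """Protein backbone heavy atoms within ``cutoff`` of the ligand centroid."""

    atom_keys: tuple[tuple[str, int, str], ...]
    cutoff: float
    centroid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))

    def __len__(self) -> int:
        return len(self.atom_keys)


# ---------------------------------------------------------------------------
# reading


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    for suffix, fmt in ((".pdb", "PDB"), (".ent", "PDB"), (".cif", "mmCIF"),
                        (".mmcif", "mmCIF"), (".pdbqt", "PDBQT"), (".sdf", "SDF"),
                        (".mol", "SDF")):
        if name.endswith(suffix):
            return fmt
    raise StructureParseError(f"cannot infer format from file name: {path.name}")


def _open_text(path: Path):
    if path.name.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _altloc_filter(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to altloc 'A'-first."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        cur = best.get(atom.name)
        if cur is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif (atom.occ, -ord(atom.altloc or "A")) > (cur.occ, -ord(cur.altloc or "A")):
            best[atom.name] = atom
    return [best[name] for name in order]


def _read_gemmi(path: Path, fmt: str) -> gemmi.Structure:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError with context
        raise StructureParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    return st


def _is_water(name: str) -> bool:
    return name.upper() in {"HOH", "WAT", "DOD", "H2O"}


def _gemmi_atoms(
    st: gemmi.Structure,
    remove_residues: frozenset[str],
) -> tuple[list[AtomRecord], list[list[AtomRecord]]]:
    """Split a gemmi structure into protein atoms and ligand candidate groups."""
    protein: list[AtomRecord] = []
    ligands: list[list[AtomRecord]] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            rname = residue.name.strip().upper()
            if _is_water(rname):
                continue
            info = gemmi.find_tabulated_residue(residue.name)
            is_aa = info is not None and info.is_amino_acid()
            atoms = _altloc_filter(residue)
            records = []
            for atom in atoms:
                el = atom.element.name.upper()
                if el == "H" or el == "D":
                    continue
                records.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_name=rname,
                        residue_index=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]) / ANGSTROM_PER_NM,
                        is_backbone=is_aa and atom.name in BACKBONE_NAMES,
                    )
                )
            if not records:
                continue
            if is_aa:
                protein.extend(records)
            elif rname in remove_residues or (len(records) == 1 and not is_aa):
                continue  # ions / configured removals
            else:
                ligands.append(records)
    return protein, ligands


_PDBQT_TYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "O": "O", "S": "S", "SA": "S", "P": "P", "F": "F", "CL": "Cl", "BR": "Br",
    "I": "I", "H": "H", "HD": "H", "HS": "H", "ZN": "Zn", "MG": "Mg", "CA": "Ca",
    "MN": "Mn", "FE": "Fe",
}


def _parse_pdbqt(path: Path) -> tuple[list[AtomRecord], list[list[AtomRecord]]]:
    """Coordinate-only PDBQT reader; charge and type columns are ignored.

    Poses written by docking engines carry the ligand as HETATM or bare ATOM
    records; only the first MODEL of a multi-model file is read.
    """
    protein: list[AtomRecord] = []
    hetero: dict[tuple[str, int, str], list[AtomRecord]] = {}
    in_model = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model += 1
                if in_model > 1:
                    break
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:21].strip().upper() or "LIG"
                chain = line[21].strip() or "A"
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise StructureParseError(f"{path}:{lineno}: bad {rec} record") from exc
            ad_type = line[77:].strip().split()[0].upper() if line[77:].strip() else ""
            element = _PDBQT_TYPE_TO_ELEMENT.get(ad_type)
            if element is None:
                element = (name[:2].capitalize() if name[:2].upper() in ("CL", "BR") else name[:1].upper())
            if element == "H":
                continue
            if _is_water(resname):
                continue
            is_aa = resname in STANDARD_AA
            atom = AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_index=resseq,
                chain_id=chain,
                position=np.array([x, y, z]) / ANGSTROM_PER_NM,
                is_backbone=is_aa and name in BACKBONE_NAMES,
            )
            if is_aa:
                protein.append(atom)
            else:
                hetero.setdefault((chain, resseq, resname), []).append(atom)
    return protein, list(hetero.values())


def read_ligand_sdf(path: str | Path, ligand_id: str | None = None) -> list[AtomRecord]:
    """Read the first molecule of an SDF/MOL file as ligand heavy atoms (nm)."""
    from rdkit import Chem

    path = Path(path)
    with _open_text(path) as fh:
        block = fh.read()
    mol = Chem.MolFromMolBlock(block, removeHs=True, sanitize=False)
    if mol is None:
        raise StructureParseError(f"{path}: RDKit could not parse MOL/SDF block")
    conf = mol.GetConformer()
    name_counts: dict[str, int] = {}
    records = []
    lig = ligand_id or (mol.GetProp("_Name").strip() if mol.HasProp("_Name") else "") or "LIG"
    for i, a in enumerate(mol.GetAtoms()):
        el = a.GetSymbol()
        if el == "H":
            continue
        n = name_counts.get(el, 0) + 1
        name_counts[el] = n
        p = conf.GetAtomPosition(i)
        records.append(
            AtomRecord(
                serial=i + 1,
                name=f"{el.upper()}{n}",
                element=el,
                residue_name=lig,
                residue_index=1,
                chain_id="L",
                position=np.array([p.x, p.y, p.z]) / ANGSTROM_PER_NM,
                is_backbone=False,
            )
        )
    if not records:
        raise EmptyLigandError(f"{path}: no heavy atoms in SDF molecule")
    return records


def _select_ligand(
    groups: list[list[AtomRecord]],
    selector,
    strict: bool,
    context: str,
) -> list[AtomRecord]:
    if not groups:
        raise EmptyLigandError(f"{context}: no ligand found after cleaning")
    code = None
    instance = 0
    if selector is not None:
        if isinstance(selector, tuple):
            code, instance = selector[0], int(selector[1])
        elif isinstance(selector, int):
            instance = selector
        else:
            code = str(selector)
    if code is not None:
        groups = [g for g in groups if g[0].residue_name == code.upper()]
        if not groups:
            raise EmptyLigandError(f"{context}: no ligand with component code {code!r}")
    if len(groups) > 1 and selector is None and strict:
        codes = sorted({g[0].residue_name for g in groups})
        raise AmbiguousLigandError(
            f"{context}: {len(groups)} ligand copies present ({', '.join(codes)}); "
            "pass ligand_selector or disable strict mode"
        )
    try:
        return groups[instance]
    except IndexError:
        raise EmptyLigandError(f"{context}: ligand instance {instance} out of range") from None


def read_complex(
    path: str | Path,
    format: str | None = None,
    ligand_selector=None,
    *,
    ligand_path: str | Path | None = None,
    strict: bool = True,
    entry_id: str | None = None,
    remove_residues: Iterable[str] = DEFAULT_REMOVE,
) -> Complex:
    """Read a protein--ligand complex and clean it.

    Parameters
    ----------
    path
        Structure file (PDB, mmCIF or PDBQT; ``.gz`` accepted).
    format
        One of ``PDB``, ``mmCIF``, ``PDBQT``; inferred from the suffix if omitted.
    ligand_selector
        Component code (``"8PF"``), instance index, or ``(code, index)`` tuple
        picking one ligand copy when several are present.
    ligand_path
        Optional SDF file supplying the ligand separately (``SDF+coords`` source).
    strict
        Require exactly one ligand copy unless a selector disambiguates.

    Hydrogens, waters, monoatomic ions and hetero groups other than the
    selected ligand are dropped; coordinates are converted from Angstrom to nm.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = (format or _detect_format(path)).upper()
    if fmt == "MMCIF":
        fmt = "mmCIF"
    remove = frozenset(r.upper() for r in remove_residues)

    if fmt in ("PDB", "mmCIF"):
        st = _read_gemmi(path, fmt)
        protein, groups = _gemmi_atoms(st, remove)
        default_entry = st.name or path.stem
    elif fmt == "PDBQT":
        protein, groups = _parse_pdbqt(path)
        default_entry = path.stem
    else:
        raise StructureParseError(f"unsupported complex format: {fmt}")

    if ligand_path is not None:
        ligand = read_ligand_sdf(ligand_path)
        fmt = "SDF+coords"
    else:
        ligand = _select_ligand(groups, ligand_selector, strict, str(path))

    return Complex(
        entry_id=entry_id or default_entry,
        ligand_id=ligand[0].residue_name,
        protein_atoms=protein,
        ligand_atoms=ligand,
        source_format=fmt,
    )


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(complex: Complex) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = complex.entry_id
    model = gemmi.Model("1")
    serial = 0
    chains: dict[str, gemmi.Chain] = {}

    def flush(cid: str, residue: gemmi.Residue | None) -> None:
        if residue is None:
            return
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        chains[cid].add_residue(residue)  # gemmi copies: residue must be complete

    def put(atoms: Sequence[AtomRecord]) -> None:
        nonlocal serial
        current = None  # (chain, residue_index, residue_name)
        residue = None
        for a in atoms:
            cid = a.chain_id or "A"
            marker = (cid, a.residue_index, a.residue_name)
            if marker != current:
                if current is not None:
                    flush(current[0], residue)
                residue = gemmi.Residue()
                residue.name = a.residue_name
                residue.seqid = gemmi.SeqId(a.residue_index, " ")
                current = marker
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            serial += 1
            atom.serial = serial  # renumbered 1..N on write; >99999 handled hybrid-36 by gemmi
            xyz = a.position * ANGSTROM_PER_NM
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            residue.add_atom(atom)
        if current is not None:
            flush(current[0], residue)

    put(complex.protein_atoms)
    put(complex.ligand_atoms)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_complex(complex: Complex, path: str | Path, format: str | None = None) -> None:
    """Write the complex as PDB or mmCIF, convertible back by :func:`read_complex`.

    Atom serials are renumbered sequentially; files over 99,999 atoms rely on
    gemmi's hybrid-36 serial encoding, which :func:`read_complex` also decodes.
    """
    path = Path(path)
    fmt = (format or _detect_format(path)).upper()
    st = _to_gemmi(complex)
    try:
        if fmt == "PDB":
            st.write_pdb(str(path))
        elif fmt in ("MMCIF", "CIF"):
            st.make_mmcif_document().write_file(str(path))
        else:
            raise StructureError(f"unsupported output format: {fmt}")
    except OSError as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# pocket


def define_pocket(native: Complex, cutoff: float = 1.0) -> PocketSelection:
    """Select protein backbone heavy atoms within ``cutoff`` nm (inclusive) of
    the geometric centre of the native ligand's heavy atoms."""
    ligand = np.array([a.position for a in native.ligand_atoms if a.is_heavy])
    if ligand.size == 0:
        raise EmptyLigandError(f"{native.entry_id}: no ligand heavy atoms")
    centroid = ligand.mean(axis=0)
    backbone = native.backbone_atoms()
    if not backbone:
        raise StructureError(f"{native.entry_id}: no backbone heavy atoms")
    keys = tuple(
        a.key for a in backbone if np.linalg.norm(a.position - centroid) <= cutoff
    )
    if not keys:
        warnings.warn(
            f"{native.entry_id}: empty pocket at cutoff {cutoff} nm; "
            "pocket-based metrics will refuse this selection",
            stacklevel=2,
        )
    return PocketSelection(atom_keys=keys, cutoff=cutoff, centroid=centroid)
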