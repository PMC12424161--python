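"""PFAS structural classification, chain length, and net-charge category.

Per- and polyfluoroalkyl substances are screened here under three structural
definitions that differ in breadth:

* **OECD (2021)**: the molecule contains at least one fully fluorinated
  saturated carbon, i.e. a -CF2- or -CF3 group (>= 2 fluorines, no hydrogen,
  non-aromatic, all single bonds).
* **EPA OPPT**: the stricter two-carbon motif -CF2-CF<, a fully fluorinated
  CF2 carbon bonded to another saturated carbon bearing at least one
  fluorine.  Every EPA match is therefore also an OECD match.  A looser
  -CF-CF- reading (one fluorine on each carbon) is available behind
  ``epa_loose=True``.
* **Aromatic fluorine (-Ph-F)**: a fluorine bonded directly to an aromatic
  carbon.

Chain length is the number of carbons on the longest simple path through
carbon-carbon bonds (the carboxyl/head carbon counts), matching how the
homologous perfluorocarboxylic acids PFHpA/PFOA/PFNA are labelled C7/C8/C9.

The charge category is a deliberately simple rule model of the pH 7.4
protonation state: carboxylic, sulfonic, sulfate and phosphonate groups
contribute -1 each, aliphatic amines and quaternary ammonium +1 each, and
the sign of the sum gives {negative, neutral, positive}.  It reproduces the
protonation-tool categories for the ligand classes handled here without
attempting pKa prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeGraph",
    "PFASProfile",
    "ChemistryError",
    "classify_motifs",
    "chain_length",
    "charge_category",
    "profile",
    "ccd_lookup",
]


class ChemistryError(ValueError):
    pass


def _load_ccd_table() -> dict[str, dict[str, str]]:
    with resources.files("pfaseval.data").joinpath("ccd_pfas.json").open() as fh:
        return json.load(fh)


@dataclass
class MoleculeGraph:
    """A small-molecule graph with the annotations classification needs.

    ``atoms`` holds (element, aromatic flag, formal charge, hydrogen count)
    per heavy atom; ``bonds`` holds (i, j, order, aromatic flag).  The
    wrapped RDKit molecule is retained for substructure queries.
    """

    atoms: list[tuple[str, bool, int, int]]
    bonds: list[tuple[int, int, float, bool]]
    name: str = ""
    source: str = "SMILES"
    _mol: Chem.Mol | None = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "", source: str = "SMILES") -> "MoleculeGraph":
        mol = Chem.RemoveHs(mol)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            warnings.warn(
                f"{name or 'molecule'}: {len(frags)} fragments; classifying the largest",
                stacklevel=3,
            )
            mol = max(frags, key=lambda m: m.GetNumAtoms())
        atoms = [
            (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble(), b.GetIsAromatic())
            for b in mol.GetBonds()
        ]
        return cls(atoms=atoms, bonds=bonds, name=name, source=source, _mol=mol)

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MoleculeGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemistryError(f"RDKit could not parse SMILES: {smiles!r}")
        return cls.from_rdkit(mol, name=name or smiles, source="SMILES")

    @classmethod
    def from_sdf(cls, path: str | Path, name: str = "") -> "MoleculeGraph":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None:
            raise ChemistryError(f"no parseable molecule in {path}")
        return cls.from_rdkit(mol, name=name or Path(path).stem, source="SDF")

    @classmethod
    def from_ccd(cls, code: str) -> "MoleculeGraph":
        """Resolve a PDB chemical-component code via the bundled lookup table.

        The table covers the perfluoroalkyl acids this package ships examples
        for (8PF, 4EI, 4I6, P8S, TFA, ...); it is not a general CCD client.
        """
        table = _load_ccd_table()
        entry = table.get(code.upper())
        if entry is None:
            raise ChemistryError(
                f"component code {code!r} not in the bundled PFAS lookup "
                f"(known: {', '.join(sorted(table))})"
            )
        return cls.from_smiles(entry["smiles"], name=code.upper())

    # -- helpers ----------------------------------------------------------

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            self._mol = self._rebuild()
        return self._mol

    def _rebuild(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for element, aromatic, charge, n_h in self.atoms:
            atom = Chem.Atom(element)
            atom.SetIsAromatic(aromatic)
            atom.SetFormalCharge(charge)
            atom.SetNumExplicitHs(n_h)
            rw.AddAtom(atom)
        order_map = {1.0: Chem.BondType.SINGLE, 1.5: Chem.BondType.AROMATIC,
                     2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}
        for i, j, order, aromatic in self.bonds:
            rw.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def carbon_neighbors(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {
            i: [] for i, (el, *_r) in enumerate(self.atoms) if el == "C"
        }
        for i, j, _order, _arom in self.bonds:
            if i in adj and j in adj:
                adj[i].append(j)
                adj[j].append(i)
        return adj


@dataclass(frozen=True)
class PFASProfile:
    """Classification outcome for one ligand."""

    oecd: bool
    epa_cf2cf: bool
    aromatic_f: bool
    chain_length: int
    charge_category: str  # negative | neutral | positive

    def __post_init__(self) -> None:
        if self.epa_cf2cf and not self.oecd:
            raise ChemistryError("invariant violated: EPA -CF2-CF< implies OECD -CF2-/-CF3")
        if self.charge_category not in ("negative", "neutral", "positive"):
            raise ChemistryError(f"bad charge category {self.charge_category!r}")


def _atom_env(mol: Chem.Mol):
    """Per heavy atom: (is_carbon, aromatic, saturated, n_fluorine, n_hydrogen)."""
    env = []
    for atom in mol.GetAtoms():
        saturated = not atom.GetIsAromatic() and all(
            b.GetBondType() == Chem.BondType.SINGLE for b in atom.GetBonds()
        )
        n_f = sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "F")
        env.append(
            (atom.GetSymbol() == "C", atom.GetIsAromatic(), saturated, n_f, atom.GetTotalNumHs())
        )
    return env


def classify_motifs(mol: MoleculeGraph, epa_loose: bool = False) -> tuple[bool, bool, bool]:
    """Return (oecd, epa_cf2cf, aromatic_f) for the molecule.

    ``epa_loose`` switches the EPA motif to the -CF-CF- reading (>= 1 fluorine
    on each of two bonded saturated carbons) instead of the default -CF2-CF<.
    """
    m = mol.mol
    env = _atom_env(m)
    oecd = any(
        is_c and sat and n_f >= 2 and n_h == 0
        for is_c, _arom, sat, n_f, n_h in env
    )
    epa = False
    for bond in m.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for a, b in ((i, j), (j, i)):
            c1, c2 = env[a], env[b]
            if not (c1[0] and c2[0] and c1[2] and c2[2]):
                continue  # both ends must be saturated carbons
            if epa_loose:
                if c1[3] >= 1 and c2[3] >= 1:
                    epa = True
            elif c1[3] >= 2 and c1[4] == 0 and c2[3] >= 1:
                epa = True
        if epa:
            break
    aromatic_f = any(
        atom.GetSymbol() == "F"
        and any(nb.GetIsAromatic() and nb.GetSymbol() == "C" for nb in atom.GetNeighbors())
        for atom in m.GetAtoms()
    )
    return oecd, epa, aromatic_f


def chain_length(mol: MoleculeGraph) -> int:
    """Number of carbons on the longest simple carbon-carbon path."""
    adj = mol.carbon_neighbors()
    if not adj:
        return 0
    best = 1

    def dfs(node: int, visited: set[int]) -> int:
        length = 1
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                length = max(length, 1 + dfs(nb, visited))
                visited.remove(nb)
        return length

    for start in adj:
        best = max(best, dfs(start, {start}))
    return best


_ACID_SMARTS = {
    "carboxyl": Chem.MolFromSmarts("[CX3](=O)[OX2H1,OX1-]"),
    "sulfonic_or_sulfate": Chem.MolFromSmarts("[SX4](=O)(=O)[OX2H1,OX1-]"),
    "phosphonate": Chem.MolFromSmarts("[PX4](=O)[OX2H1,OX1-]"),
}
_BASE_SMARTS = {
    "aliphatic_amine": Chem.MolFromSmarts(
        "[NX3;!$([NX3]-[CX3]=[O,N,S]);!$([NX3]-[SX4]=O);!$([NX3]-a);!$([NX3]=*);!$([NX3]#*)]"
    ),
    "quaternary_ammonium": Chem.MolFromSmarts("[NX4+]"),
}


def charge_category(mol: MoleculeGraph, pH: float = 7.4) -> str:
    """Net-charge category at the given pH under the rule model.

    Only pH 7.4 rules are implemented; other pH values raise, rather than
    silently reusing rules derived for physiological conditions.
    """
    if abs(pH - 7.4) > 1e-9:
        raise ChemistryError("the rule-based charge model is defined at pH 7.4 only")
    m = mol.mol
    net = 0
    for pattern in _ACID_SMARTS.values():
        # one charge per acidic centre (first matched atom), not per tautomer match
        centres = {match[0] for match in m.GetSubstructMatches(pattern)}
        net -= len(centres)
    for pattern in _BASE_SMARTS.values():
        centres = {match[0] for match in m.GetSubstructMatches(pattern)}
        net += len(centres)
    if net < 0:
        return "negative"
    if net > 0:
        return "positive"
    return "neutral"


def profile(mol: MoleculeGraph, epa_loose: bool = False) -> PFASProfile:
    """Full classification: motifs, chain length and charge category."""
    oecd, epa, aromatic_f = classify_motifs(mol, epa_loose=epa_loose)
    return PFASProfile(
        oecd=oecd,
        epa_cf2cf=epa,
        aromatic_f=aromatic_f,
        chain_length=chain_length(mol),
        charge_category=charge_category(mol),
    )


def ccd_lookup() -> dict[str, dict[str, str]]:
    """The bundled component-code table (code -> {smiles, name})."""
    return _load_ccd_table()
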