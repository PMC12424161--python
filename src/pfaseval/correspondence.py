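"""Native-to-predicted atom pairing.

RMSD metrics need an explicit one-to-one correspondence between atoms of the
experimental (native) complex and a predicted complex.  Predicted files are
frequently renumbered and re-chained, so protein residues are paired by
global pairwise sequence alignment of one-letter sequences and backbone
atoms by (aligned residue, atom name).  Ligand atoms are paired either by
atom name / file order, or by searching the ligand graph's automorphisms for
the chemically equivalent relabelling that minimises ligand-aligned RMSD
(``symmetry_min``) -- relevant for PFAS, whose terminal CF3 fluorines are
indistinguishable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from Bio import Align

from .structure_io import AtomRecord, Complex, PocketSelection

__all__ = [
    "Correspondence",
    "CorrespondenceError",
    "SequenceMismatchError",
    "IncompatibleLigandError",
    "map_protein_atoms",
    "map_ligand_atoms",
    "build_correspondence",
    "ligand_graph_from_positions",
]

AtomKey = tuple[str, int, str]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Covalent radii (nm) for distance-based bond perception of ligand graphs.
_COVALENT_RADII = {
    "H": 0.031, "C": 0.076, "N": 0.071, "O": 0.066, "F": 0.057,
    "P": 0.107, "S": 0.105, "CL": 0.102, "BR": 0.120, "I": 0.139,
}


class CorrespondenceError(ValueError):
    pass


class SequenceMismatchError(CorrespondenceError):
    """Aligned sequence identity too low -- files probably do not belong together."""


class IncompatibleLigandError(CorrespondenceError):
    """Ligands differ in heavy-atom count or element composition."""


@dataclass
class Correspondence:
    """Validated one-to-one pairing of native and predicted atoms."""

    protein_pairs: list[tuple[AtomKey, AtomKey]]
    ligand_pairs: list[tuple[AtomKey, AtomKey]]
    method: str = "name_order"

    def __post_init__(self) -> None:
        for pairs, label in ((self.protein_pairs, "protein"), (self.ligand_pairs, "ligand")):
            left = [p[0] for p in pairs]
            right = [p[1] for p in pairs]
            if len(set(left)) != len(left) or len(set(right)) != len(right):
                raise CorrespondenceError(f"{label} pairing is not injective")

    def resolve(
        self,
        native: Complex,
        predicted: Complex,
        selection: Sequence[AtomKey] | None = None,
        which: str = "protein",
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Return paired coordinate arrays (native, predicted) restricted to
        ``selection`` native keys, plus the fraction of the selection resolved."""
        pairs = self.protein_pairs if which == "protein" else self.ligand_pairs
        mapping = dict(pairs)
        nat_atoms = native.atom_by_key()
        pred_atoms = predicted.atom_by_key()
        keys = list(selection) if selection is not None else [p[0] for p in pairs]
        nat, pred = [], []
        for k in keys:
            pk = mapping.get(k)
            if pk is None:
                continue
            nat.append(nat_atoms[k].position)
            pred.append(pred_atoms[pk].position)
        coverage = len(nat) / len(keys) if keys else 0.0
        return np.array(nat), np.array(pred), coverage

    def pocket_coverage(self, pocket: PocketSelection) -> float:
        mapping = dict(self.protein_pairs)
        if not pocket.atom_keys:
            return 0.0
        return sum(1 for k in pocket.atom_keys if k in mapping) / len(pocket.atom_keys)


# ---------------------------------------------------------------------------
# protein pairing


def _chain_residues(complex: Complex) -> dict[str, list[tuple[int, str, dict[str, AtomRecord]]]]:
    """Per chain: ordered (residue_index, residue_name, backbone atoms by name)."""
    chains: dict[str, dict[int, tuple[str, dict[str, AtomRecord]]]] = {}
    for atom in complex.protein_atoms:
        if not atom.is_backbone:
            continue
        res = chains.setdefault(atom.chain_id, {}).setdefault(
            atom.residue_index, (atom.residue_name, {})
        )
        res[1][atom.name] = atom
    out = {}
    for cid, residues in chains.items():
        out[cid] = [(idx, rname, atoms) for idx, (rname, atoms) in sorted(residues.items())]
    return out


def _sequence(residues) -> str:
    return "".join(THREE_TO_ONE.get(rname, "X") for _, rname, _ in residues)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def map_protein_atoms(
    native: Complex,
    predicted: Complex,
    min_identity: float = 0.90,
) -> list[tuple[AtomKey, AtomKey]]:
    """Pair backbone heavy atoms through global sequence alignment.

    Chains are matched greedily by alignment score; residues are paired by the
    alignment and atoms within aligned residues by name.  Residues absent from
    one side (e.g. unmodelled termini) are simply left unpaired.

    Raises
    ------
    SequenceMismatchError
        If overall aligned identity falls below ``min_identity`` (default 90%),
        which almost always means the two files describe different proteins.
    """
    nat_chains = _chain_residues(native)
    pred_chains = _chain_residues(predicted)
    if not nat_chains or not pred_chains:
        raise CorrespondenceError("both complexes need at least one protein chain")

    aligner = _make_aligner()
    # greedy chain matching by alignment score
    scored = []
    for nc, nres in nat_chains.items():
        for pc, pres in pred_chains.items():
            score = aligner.score(_sequence(nres), _sequence(pres))
            scored.append((score, nc, pc))
    scored.sort(reverse=True)
    used_n: set[str] = set()
    used_p: set[str] = set()
    chain_pairs = []
    for score, nc, pc in scored:
        if nc in used_n or pc in used_p:
            continue
        used_n.add(nc)
        used_p.add(pc)
        chain_pairs.append((nc, pc))

    pairs: list[tuple[AtomKey, AtomKey]] = []
    matches = 0
    aligned_cols = 0
    for nc, pc in chain_pairs:
        nres = nat_chains[nc]
        pres = pred_chains[pc]
        alignment = aligner.align(_sequence(nres), _sequence(pres))[0]
        for (ns, ne), (ps, pe) in zip(*alignment.aligned):
            for offset in range(ne - ns):
                ni, rname_n, natoms = nres[ns + offset]
                pi, rname_p, patoms = pres[ps + offset]
                aligned_cols += 1
                if rname_n == rname_p:
                    matches += 1
                for name, atom in natoms.items():
                    patom = patoms.get(name)
                    if patom is not None:
                        pairs.append((atom.key, patom.key))
    if aligned_cols == 0:
        raise SequenceMismatchError("sequence alignment produced no aligned residues")
    identity = matches / aligned_cols
    if identity < min_identity:
        raise SequenceMismatchError(
            f"aligned sequence identity {identity:.1%} below {min_identity:.0%}; "
            "native and predicted files likely mismatched"
        )
    return pairs


# ---------------------------------------------------------------------------
# ligand pairing


def ligand_graph_from_positions(atoms: Sequence[AtomRecord], slack: float = 0.045) -> nx.Graph:
    """Perceive a bond graph from heavy-atom coordinates via covalent radii.

    Two atoms are bonded when their distance is below the sum of covalent
    radii plus ``slack`` (nm).  Adequate for the near-ideal geometries this
    package works with; not a general bond-perception routine.
    """
    g = nx.Graph()
    for i, a in enumerate(atoms):
        g.add_node(i, element=a.element.upper())
    for i in range(len(atoms)):
        ri = _COVALENT_RADII.get(atoms[i].element.upper(), 0.077)
        for j in range(i + 1, len(atoms)):
            rj = _COVALENT_RADII.get(atoms[j].element.upper(), 0.077)
            d = float(np.linalg.norm(atoms[i].position - atoms[j].position))
            if d <= ri + rj + slack:
                g.add_edge(i, j)
    return g


def _fit_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    # local Kabsch to score candidate pairings without importing pose_metrics
    ca, cb = a - a.mean(0), b - b.mean(0)
    u, s, vt = np.linalg.svd(cb.T @ ca)
    d = np.sign(np.linalg.det(u @ vt))
    s[-1] *= d
    msd = max((ca**2).sum() + (cb**2).sum() - 2 * s.sum(), 0.0) / len(a)
    return float(np.sqrt(msd / 1.0))


def _automorphisms(graph: nx.Graph, limit: int) -> list[dict[int, int]] | None:
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        graph, graph, node_match=lambda x, y: x["element"] == y["element"]
    )
    autos = []
    for mapping in matcher.isomorphisms_iter():
        autos.append(mapping)
        if len(autos) > limit:
            return None
    return autos


def map_ligand_atoms(
    native: Complex,
    predicted: Complex,
    mode: str = "name_order",
    topology: nx.Graph | None = None,
    automorphism_limit: int = 10_000,
) -> list[tuple[AtomKey, AtomKey]]:
    """Pair ligand heavy atoms between native and predicted complexes.

    ``name_order`` pairs by atom name when names are unique on both sides and
    agree as sets, otherwise by file order.  ``symmetry_min`` additionally
    enumerates element-preserving automorphisms of the ligand bond graph
    (supplied via ``topology`` or perceived from native coordinates) and keeps
    the relabelling with the smallest ligand-aligned RMSD, so chemically
    equivalent atoms (e.g. CF3 fluorines) cannot inflate the metric.
    """
    nat = native.ligand_atoms
    pred = predicted.ligand_atoms
    if len(nat) != len(pred):
        raise IncompatibleLigandError(
            f"ligand heavy-atom counts differ: {len(nat)} vs {len(pred)}"
        )
    if sorted(a.element.upper() for a in nat) != sorted(a.element.upper() for a in pred):
        raise IncompatibleLigandError("ligand element compositions differ")

    nat_names = [a.name for a in nat]
    pred_names = [a.name for a in pred]
    by_name_ok = (
        len(set(nat_names)) == len(nat_names)
        and set(nat_names) == set(pred_names)
    )
    if by_name_ok:
        pred_by_name = {a.name: a for a in pred}
        order_pairs = [(a, pred_by_name[a.name]) for a in nat]
    else:
        order_pairs = list(zip(nat, pred))
    for a, b in order_pairs:
        if a.element.upper() != b.element.upper():
            raise IncompatibleLigandError(
                f"paired atoms {a.name}/{b.name} have different elements"
            )

    if mode == "name_order":
        return [(a.key, b.key) for a, b in order_pairs]
    if mode != "symmetry_min":
        raise CorrespondenceError(f"unknown ligand pairing mode: {mode}")

    graph = topology if topology is not None else ligand_graph_from_positions(nat)
    if set(graph.nodes) != set(range(len(nat))):
        raise CorrespondenceError("topology graph nodes must index native ligand atoms 0..n-1")
    autos = _automorphisms(graph, automorphism_limit)
    if autos is None:
        warnings.warn(
            f"more than {automorphism_limit} ligand automorphisms; "
            "falling back to name_order pairing",
            stacklevel=2,
        )
        return [(a.key, b.key) for a, b in order_pairs]

    # baseline pairing as index map native_i -> predicted atom
    base_pred = [b for _, b in order_pairs]
    nat_coords = np.array([a.position for a in nat])
    best_pairs = None
    best_rmsd = np.inf
    for auto in autos:
        pred_perm = [base_pred[auto[i]] for i in range(len(nat))]
        rmsd = _fit_rmsd(nat_coords, np.array([b.position for b in pred_perm]))
        if rmsd < best_rmsd - 1e-12:
            best_rmsd = rmsd
            best_pairs = [(nat[i].key, pred_perm[i].key) for i in range(len(nat))]
    assert best_pairs is not None
    return best_pairs


def build_correspondence(
    native: Complex,
    predicted: Complex,
    ligand_mode: str = "name_order",
    topology: nx.Graph | None = None,
    min_identity: float = 0.90,
) -> Correspondence:
    """Protein and ligand pairings combined into one :class:`Correspondence`."""
    return Correspondence(
        protein_pairs=map_protein_atoms(native, predicted, min_identity=min_identity),
        ligand_pairs=map_ligand_atoms(native, predicted, mode=ligand_mode, topology=topology),
        method=ligand_mode,
    )
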