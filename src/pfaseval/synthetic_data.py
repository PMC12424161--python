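"""Deterministic toy complexes and perturbed poses with known error modes.

Real native/predicted complex pairs require structure downloads and docking
engines; this module builds geometrically exact stand-ins instead:

* a poly-alanine ideal alpha-helix (backbone heavy atoms N, CA, C, O) as the
  protein -- metrics in this package use backbone atoms only, so side-chain
  realism is deliberately not attempted;
* a linear all-anti perfluoroalkyl ligand with a carboxylate headgroup
  (chain length k gives the perfluorocarboxylate topology C_k F_{2k-1} O_2),
  built with exact tetrahedral fluorine geometry and parked against the
  helix so the 1 nm pocket is never empty.

``perturb`` then injects exactly one error mode with a known magnitude --
global rigid motion (harmless by construction), rigid ligand displacement
(pure placement error), an internal ligand torsion kick (ligand-structure
error), or Gaussian pocket noise (pocket-structure error) -- so every
metric and every failure-mode classification has a ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .correspondence import ligand_graph_from_positions
from .structure_io import AtomRecord, Complex, define_pocket

__all__ = [
    "PerturbationSpec",
    "CohortSpec",
    "make_toy_complex",
    "perturb",
    "failure_perturbation",
    "make_failure_cohort",
    "make_evaluation_table",
]

MODES = ("global_rigid", "ligand_rigid", "ligand_internal", "pocket_noise", "combined")

# geometry constants (nm, degrees)
CC_BOND = 0.154
CF_BOND = 0.135
CO_BOND = 0.125
TETRA = math.radians(109.4712206)
HELIX_RISE = 0.15
HELIX_TURN = math.radians(100.0)
HELIX_RADIUS = 0.23


@dataclass(frozen=True)
class PerturbationSpec:
    """One controlled error mode.

    ``magnitude`` is in nm for ``ligand_rigid`` (translation distance) and
    ``pocket_noise`` (per-coordinate Gaussian sigma), and in degrees for
    ``global_rigid`` (rotation angle) and ``ligand_internal`` (torsion kick).
    ``combined`` applies ligand_rigid and pocket_noise, reading magnitude as
    nm for both.  ``n_kicks`` (ligand_internal only) applies the torsion
    rotation to that many distinct internal C-C bonds with random sign; a
    nearly linear perfluoroalkyl chain needs several compounded kicks before
    its internal geometry deviates strongly.
    """

    mode: str
    magnitude: float
    seed: int
    pocket_cutoff: float = 1.0
    n_kicks: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown perturbation mode {self.mode!r}; choose from {MODES}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.n_kicks < 1:
            raise ValueError("n_kicks must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic evaluation cohort.

    ``success_probs`` gives the per-split probability that any one pose is a
    success under the pocket-aligned reference; ``mode_mixture`` distributes
    failed poses over the three substantive failure sources.
    """

    n_systems: int = 100
    success_probs: dict = field(
        default_factory=lambda: {"Before": 0.745, "After": 0.558}
    )
    mode_mixture: dict = field(
        default_factory=lambda: {
            "ligand_rigid": 0.6, "ligand_internal": 0.25, "pocket_noise": 0.15
        }
    )
    charge_probs: dict = field(
        default_factory=lambda: {"negative": 0.7, "neutral": 0.2, "positive": 0.1}
    )
    methods: tuple = ("AF3",)
    n_poses: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (("success_probs", self.success_probs.values()),
                            ("mode_mixture", [sum(self.mode_mixture.values())]),
                            ("charge_probs", [sum(self.charge_probs.values())])):
            for p in probs:
                if not (0 <= p <= 1.0000001):
                    raise ValueError(f"{name}: probabilities must lie in [0, 1]")
        if abs(sum(self.mode_mixture.values()) - 1) > 1e-9:
            raise ValueError("mode_mixture must sum to 1")
        if abs(sum(self.charge_probs.values()) - 1) > 1e-9:
            raise ValueError("charge_probs must sum to 1")


# ---------------------------------------------------------------------------
# geometry helpers


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def _orthonormal_frame(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = a / np.linalg.norm(a)
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def _tetrahedral_completion(c: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions of the two remaining tetrahedral substituents of a
    carbon at ``c`` already bonded towards ``n1`` and ``n2`` (exact)."""
    a = (n1 - c) / np.linalg.norm(n1 - c)
    b = (n2 - c) / np.linalg.norm(n2 - c)
    p = -(a + b)
    p /= np.linalg.norm(p)
    q = np.cross(a, b)
    q /= np.linalg.norm(q)
    phi = 0.5 * TETRA
    return p * math.cos(phi) + q * math.sin(phi), p * math.cos(phi) - q * math.sin(phi)


# ---------------------------------------------------------------------------
# toy complex


def make_toy_complex(
    seed: int = 0,
    n_residues: int = 20,
    ligand_chain_length: int = 8,
    ligand_id: str = "PFA",
) -> Complex:
    """Ideal-helix poly-alanine protein plus a perfluorocarboxylate ligand.

    The ligand (carbon count ``ligand_chain_length``, carboxylate head on C1,
    CF3 tail) is placed parallel to the helix axis, 0.5 nm off it, centred at
    the axis midpoint; the seed only rotates its azimuthal placement, so the
    output is a pure function of (seed, n_residues, ligand_chain_length).
    """
    if n_residues < 20:
        raise ValueError("n_residues must be >= 20")
    if ligand_chain_length < 2:
        raise ValueError("ligand_chain_length must be >= 2")
    rng = np.random.default_rng(seed)

    protein: list[AtomRecord] = []
    serial = 0
    for i in range(n_residues):
        theta = i * HELIX_TURN
        rot = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), theta)
        ca = np.array(
            [HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta), i * HELIX_RISE]
        )
        local = {
            "N": np.array([-0.12, -0.05, -0.06]),
            "C": np.array([0.12, 0.05, 0.06]),
            "O": np.array([0.14, 0.16, 0.06]),
        }
        for name in ("N", "CA", "C", "O"):
            pos = ca if name == "CA" else ca + rot @ local[name]
            serial += 1
            protein.append(
                AtomRecord(
                    serial=serial, name=name, element="N" if name == "N" else
                    ("O" if name == "O" else "C"),
                    residue_name="ALA", residue_index=i + 1, chain_id="A",
                    position=pos, is_backbone=True,
                )
            )

    k = ligand_chain_length
    azimuth = rng.uniform(0.0, 2.0 * math.pi)
    offset_dir = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    d_ax = CC_BOND * math.sin(TETRA / 2.0)
    d_lat = CC_BOND * math.cos(TETRA / 2.0)
    z_mid = (n_residues - 1) * HELIX_RISE / 2.0
    z0 = z_mid - (k - 1) * d_ax / 2.0
    lat_dir, _ = _orthonormal_frame(np.array([0.0, 0.0, 1.0]))
    # rotate the zigzag's lateral direction with the azimuth for variety
    lat_dir = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), azimuth) @ lat_dir
    carbons = [
        0.5 * offset_dir
        + np.array([0.0, 0.0, z0 + j * d_ax])
        + (0.5 * d_lat * (1 if j % 2 else -1)) * lat_dir
        for j in range(k)
    ]

    ligand: list[AtomRecord] = []

    def add(name: str, element: str, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        ligand.append(
            AtomRecord(
                serial=serial, name=name, element=element, residue_name=ligand_id,
                residue_index=1, chain_id="L", position=pos, is_backbone=False,
            )
        )

    for j, c in enumerate(carbons):
        add(f"C{j + 1}", "C", c)
    n_f = 0
    for j, c in enumerate(carbons):
        if j == 0:
            # carboxylate head: two sp2 oxygens in the C1 plane
            b = (carbons[1] - c) / np.linalg.norm(carbons[1] - c)
            e1, _ = _orthonormal_frame(b)
            for sgn, name in ((1.0, "O1"), (-1.0, "O2")):
                direction = -b * math.cos(math.radians(60)) + sgn * e1 * math.sin(
                    math.radians(60)
                )
                add(name, "O", c + CO_BOND * direction)
        elif j == k - 1:
            # CF3 tail: three fluorines staggered about the last C-C bond
            a = (c - carbons[j - 1]) / np.linalg.norm(c - carbons[j - 1])
            e1, e2 = _orthonormal_frame(a)
            for m in range(3):
                ang = 2.0 * math.pi * m / 3.0
                direction = a / 3.0 + math.sqrt(8.0) / 3.0 * (
                    e1 * math.cos(ang) + e2 * math.sin(ang)
                )
                n_f += 1
                add(f"F{n_f}", "F", c + CF_BOND * direction)
        else:
            d1, d2 = _tetrahedral_completion(c, carbons[j - 1], carbons[j + 1])
            for direction in (d1, d2):
                n_f += 1
                add(f"F{n_f}", "F", c + CF_BOND * direction)

    return Complex(
        entry_id=f"TOY{seed:04d}_{k}C",
        ligand_id=ligand_id,
        protein_atoms=protein,
        ligand_atoms=ligand,
        source_format="PDB",
    )


# ---------------------------------------------------------------------------
# perturbations


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perturb_once(native: Complex, mode: str, magnitude: float,
                  rng: np.random.Generator, pocket_cutoff: float,
                  n_kicks: int = 1) -> Complex:
    if mode == "global_rigid":
        rot = _rotation_about_axis(_random_unit(rng), math.radians(magnitude))
        trans = 0.3 * _random_unit(rng)
        return native.transformed(rot, trans)

    if mode == "ligand_rigid":
        shift = magnitude * _random_unit(rng)
        ligand = [replace(a, position=a.position + shift) for a in native.ligand_atoms]
        return replace(native, ligand_atoms=ligand)

    if mode == "ligand_internal":
        atoms = list(native.ligand_atoms)
        graph = ligand_graph_from_positions(atoms)
        carbons = {i for i, a in enumerate(atoms) if a.element == "C"}
        # rotatable bonds: C-C bridges whose smaller side moves >= 4 atoms,
        # so a kick of tens of degrees produces a substantial internal change
        candidates = []
        for i, j in graph.edges:
            if i not in carbons or j not in carbons:
                continue
            g = graph.copy()
            g.remove_edge(i, j)
            if nx.has_path(g, i, j):
                continue  # in a ring; not a torsion
            side = nx.node_connected_component(g, j)
            if min(len(side), graph.number_of_nodes() - len(side)) >= 4:
                candidates.append((i, j, frozenset(side)))
        if not candidates:
            raise ValueError("ligand too small for an internal torsion kick")
        n_kicks = min(n_kicks, len(candidates))
        chosen = rng.choice(len(candidates), size=n_kicks, replace=False)
        positions = [a.position.copy() for a in atoms]
        for c in chosen:
            i, j, side = candidates[c]
            sign = 1.0 if (n_kicks == 1 or rng.random() < 0.5) else -1.0
            axis = positions[j] - positions[i]
            rot = _rotation_about_axis(axis, sign * math.radians(magnitude))
            pivot = positions[i]
            for idx in side:
                if idx != i:
                    positions[idx] = rot @ (positions[idx] - pivot) + pivot
        ligand = [replace(a, position=positions[idx]) for idx, a in enumerate(atoms)]
        return replace(native, ligand_atoms=ligand)

    if mode == "pocket_noise":
        pocket = define_pocket(native, cutoff=pocket_cutoff)
        keys = set(pocket.atom_keys)
        protein = [
            replace(a, position=a.position + rng.normal(scale=magnitude, size=3))
            if a.key in keys
            else a
            for a in native.protein_atoms
        ]
        return replace(native, protein_atoms=protein)

    raise ValueError(f"unknown mode {mode!r}")


def perturb(native: Complex, spec: PerturbationSpec) -> Complex:
    """Apply one controlled error mode; see :class:`PerturbationSpec`."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "combined":
        out = _perturb_once(native, "ligand_rigid", spec.magnitude, rng, spec.pocket_cutoff)
        return _perturb_once(out, "pocket_noise", spec.magnitude, rng, spec.pocket_cutoff)
    return _perturb_once(native, spec.mode, spec.magnitude, rng,
                         spec.pocket_cutoff, spec.n_kicks)


#: Magnitudes that push each failure mode safely past the 0.2 nm success
#: threshold for the default C8 toy ligand.
FAILURE_MAGNITUDES = {
    "ligand_rigid": 0.5,       # nm
    "ligand_internal": 150.0,  # degrees, compounded over several bonds
    "pocket_noise": 0.35,      # nm (sigma, and ligand shift of the combined mode)
}

#: How each intended failure mode is realised as a perturbation.  Unbiased
#: iid pocket noise alone leaves the pocket superposition centred on the
#: truth, so the pose would usually still *succeed* under the pocket-aligned
#: reference; a genuine pocket-structure failure therefore pairs the noisy
#: pocket with a displaced ligand (the ``combined`` mode).
_FAILURE_REALISATION = {
    "ligand_rigid": ("ligand_rigid", dict()),
    "ligand_internal": ("ligand_internal", dict(n_kicks=5)),
    "pocket_noise": ("combined", dict()),
}


def failure_perturbation(mode: str, seed: int,
                         magnitudes: dict[str, float] | None = None) -> PerturbationSpec:
    """The perturbation spec realising a given failure mode at the default
    super-threshold magnitude."""
    magnitudes = magnitudes or FAILURE_MAGNITUDES
    perturb_mode, extra = _FAILURE_REALISATION[mode]
    return PerturbationSpec(mode=perturb_mode, magnitude=magnitudes[mode],
                            seed=seed, **extra)


def _realises_mode(native: Complex, predicted: Complex, mode: str,
                   threshold: float = 0.2) -> bool:
    from .correspondence import build_correspondence
    from .pose_metrics import evaluate_pose

    pocket = define_pocket(native)
    m = evaluate_pose(native, predicted, pocket, build_correspondence(native, predicted))
    if m.rmsd_pocket_aligned_ligand <= threshold:
        return False
    ligand_bad = m.rmsd_ligand > threshold
    pocket_bad = m.rmsd_pocket > threshold
    return {
        "ligand_rigid": not ligand_bad and not pocket_bad,
        "ligand_internal": ligand_bad and not pocket_bad,
        "pocket_noise": pocket_bad and not ligand_bad,
    }[mode]


def make_failure_cohort(
    n_systems: int,
    mixture: dict[str, float] | None = None,
    seed: int = 0,
    magnitudes: dict[str, float] | None = None,
    n_residues: int = 20,
    ligand_chain_length: int = 8,
    max_retries: int = 20,
) -> list[tuple[Complex, Complex, str]]:
    """Native/predicted pairs whose failures have known modes.

    Modes are drawn from ``mixture`` (default 60/25/15 over rigid ligand
    displacement, internal torsion error and pocket-structure error); each
    pair is guaranteed to fail the pocket-aligned criterion through exactly
    its drawn mechanism (perturbation seeds are redrawn, within the mode, in
    the rare cases where random wobble lands a pose on the wrong side of the
    threshold -- so the mode mixture itself is never distorted).
    """
    mixture = mixture or {"ligand_rigid": 0.6, "ligand_internal": 0.25, "pocket_noise": 0.15}
    magnitudes = magnitudes or FAILURE_MAGNITUDES
    modes = list(mixture)
    probs = np.array([mixture[m] for m in modes], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_systems):
        mode = modes[rng.choice(len(modes), p=probs)]
        perturb_mode, extra = _FAILURE_REALISATION[mode]
        native = make_toy_complex(
            seed=int(rng.integers(2**31)), n_residues=n_residues,
            ligand_chain_length=ligand_chain_length,
        )
        for attempt in range(max_retries):
            predicted = perturb(
                native,
                PerturbationSpec(mode=perturb_mode, magnitude=magnitudes[mode],
                                 seed=int(rng.integers(2**31)), **extra),
            )
            if _realises_mode(native, predicted, mode):
                break
        else:
            raise RuntimeError(f"could not realise failure mode {mode!r} "
                               f"in {max_retries} attempts")
        out.append((native, predicted, mode))
    return out


# ---------------------------------------------------------------------------
# synthetic evaluation tables


def make_evaluation_table(spec: CohortSpec):
    """Draw a synthetic :class:`~pfaseval.evaluation_stats.EvaluationTable`.

    Each split contributes ``n_systems`` entries with ``n_poses`` ranked
    poses per method; each pose succeeds independently with the split's
    probability.  Failed poses receive constituent RMSDs consistent with a
    failure mode drawn from ``mode_mixture`` (rigid displacement leaves
    ligand and pocket accurate; a torsion error inflates the ligand RMSD;
    pocket noise inflates the pocket RMSD), so failure-mode decomposition
    has a recoverable ground truth.  Deterministic for a fixed seed.
    """
    from .evaluation_stats import EvaluationTable

    rng = np.random.default_rng(spec.seed)
    modes = list(spec.mode_mixture)
    mode_probs = np.array([spec.mode_mixture[m] for m in modes])
    charges = list(spec.charge_probs)
    charge_probs = np.array([spec.charge_probs[c] for c in charges])
    records = []
    for split, p_success in spec.success_probs.items():
        for i in range(spec.n_systems):
            entry = f"SYN_{split}_{i:05d}"
            charge = charges[rng.choice(len(charges), p=charge_probs)]
            for method in spec.methods:
                for rank in range(1, spec.n_poses + 1):
                    success = rng.random() < p_success
                    if success:
                        pal = rng.uniform(0.02, 0.2)
                        ligand = rng.uniform(0.01, min(pal, 0.15))
                        pocket = rng.uniform(0.005, 0.1)
                    else:
                        pal = rng.uniform(0.25, 1.0)
                        mode = modes[rng.choice(len(modes), p=mode_probs)]
                        ligand = rng.uniform(0.25, 0.8) if mode == "ligand_internal" else rng.uniform(0.02, 0.15)
                        pocket = rng.uniform(0.25, 0.6) if mode == "pocket_noise" else rng.uniform(0.01, 0.1)
                    records.append(
                        {
                            "entry_id": entry,
                            "method_label": method,
                            "rank": rank,
                            "rmsd_backbone": rng.uniform(0.01, 0.15),
                            "rmsd_pocket": pocket,
                            "rmsd_ligand": ligand,
                            "rmsd_pocket_aligned_ligand": pal,
                            "split": split,
                            "charge_category": charge,
                        }
                    )
    import pandas as pd

    return EvaluationTable(pd.DataFrame(records))
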