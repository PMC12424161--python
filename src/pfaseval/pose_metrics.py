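"""Rigid-body superposition and the four alignment-reference RMSDs.

A predicted pose is judged against the native complex under four references:

``backbone``
    RMSD over all paired protein backbone heavy atoms after superposing on
    those same atoms (global fold quality).
``pocket``
    RMSD over the binding-pocket backbone atoms after superposing on the
    pocket (local pocket quality).
``ligand``
    RMSD over ligand heavy atoms after superposing the ligand onto the
    native ligand (internal ligand-geometry quality, placement ignored).
``pocket_aligned_ligand``
    The predicted complex is superposed onto the native using *pocket* atoms
    only; the resulting transform is applied to the predicted ligand and the
    ligand RMSD is taken directly, with no further fitting.  This is the
    placement-sensitive score: a perfectly built ligand parked in the wrong
    orientation scores poorly here and nowhere else.

All superpositions are unweighted least squares over heavy atoms (Kabsch,
proper rotations only).  Units are nm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .correspondence import Correspondence
from .structure_io import Complex, EmptyPocketError, PocketSelection

__all__ = [
    "RigidTransform",
    "PoseMetrics",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "aligned_rmsd",
    "pocket_aligned_ligand_rmsd",
    "evaluate_pose",
    "best_of",
    "METRIC_NAMES",
]

METRIC_NAMES = ("backbone", "pocket", "ligand", "pocket_aligned_ligand")


class DegenerateGeometryError(ValueError):
    """Fewer than 3 points, or a collinear set: the rotation is not unique."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation 3x3, translation in nm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-10:
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class PoseMetrics:
    """The four RMSDs (nm) for one predicted pose, plus bookkeeping."""

    rmsd_backbone: float
    rmsd_pocket: float
    rmsd_ligand: float
    rmsd_pocket_aligned_ligand: float
    pocket_coverage: float = 1.0
    rank: int = 1
    method_label: str = ""

    def __post_init__(self) -> None:
        for name in ("rmsd_backbone", "rmsd_pocket", "rmsd_ligand",
                     "rmsd_pocket_aligned_ligand"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")

    def metric(self, reference: str) -> float:
        return getattr(self, f"rmsd_{reference}")


def _as_points(x, label: str) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{label}: expected an (n, 3) array, got {pts.shape}")
    return pts


def kabsch_superpose(
    moving: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``moving`` onto ``reference``.

    Returns the proper rigid transform minimising the RMSD between the
    transformed moving set and the reference, together with that minimal
    RMSD.  Reflections are excluded by flipping the sign of the smallest
    singular value when the raw solution is improper.
    """
    mov = _as_points(moving, "moving")
    ref = _as_points(reference, "reference")
    if mov.shape != ref.shape:
        raise ValueError(f"point counts differ: {mov.shape[0]} vs {ref.shape[0]}")
    n = mov.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for a unique rotation, got {n}")
    cm = mov.mean(axis=0)
    cr = ref.mean(axis=0)
    x = mov - cm
    y = ref - cr
    if np.linalg.matrix_rank(x, tol=1e-9) < 2 or np.linalg.matrix_rank(y, tol=1e-9) < 2:
        raise DegenerateGeometryError("collinear point set: rotation not unique")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(diag) @ u.T
    translation = cr - rotation @ cm
    transform = RigidTransform(rotation=rotation, translation=translation)
    residual = transform.apply(mov) - ref
    rmsd = float(np.sqrt((residual**2).sum() / n))
    return transform, rmsd


def _resolved(native, predicted, selection, correspondence, which):
    nat, pred, coverage = correspondence.resolve(native, predicted, selection, which=which)
    return nat, pred, coverage


def aligned_rmsd(
    native: Complex,
    predicted: Complex,
    selection: Sequence[tuple[str, int, str]],
    correspondence: Correspondence,
    which: str = "protein",
) -> float:
    """RMSD over ``selection`` after superposing predicted onto native using
    those same atoms."""
    nat, pred, coverage = _resolved(native, predicted, selection, correspondence, which)
    if len(nat) == 0:
        raise EmptyPocketError("selection resolves to zero paired atoms")
    _, rmsd = kabsch_superpose(pred, nat)
    return rmsd


def pocket_aligned_ligand_rmsd(
    native: Complex,
    predicted: Complex,
    pocket: PocketSelection,
    correspondence: Correspondence,
) -> float:
    """Ligand RMSD in the native pocket frame, without re-fitting the ligand.

    The superposition is computed from pocket backbone atoms only and then
    applied to the predicted ligand; the heavy-atom RMSD against the native
    ligand is returned directly.
    """
    if len(pocket) == 0:
        raise EmptyPocketError("empty pocket selection")
    nat_p, pred_p, coverage = _resolved(
        native, predicted, pocket.atom_keys, correspondence, "protein"
    )
    if len(nat_p) == 0:
        raise EmptyPocketError("no pocket atoms resolvable through the correspondence")
    transform, _ = kabsch_superpose(pred_p, nat_p)
    nat_l, pred_l, lig_cov = _resolved(native, predicted, None, correspondence, "ligand")
    if len(nat_l) == 0:
        raise ValueError("no paired ligand atoms")
    moved = transform.apply(pred_l)
    return float(np.sqrt(((moved - nat_l) ** 2).sum() / len(nat_l)))


def evaluate_pose(
    native: Complex,
    predicted: Complex,
    pocket: PocketSelection,
    correspondence: Correspondence,
    rank: int = 1,
    method_label: str = "",
) -> PoseMetrics:
    """Compute all four alignment-reference RMSDs for one predicted pose."""
    backbone_keys = [a.key for a in native.backbone_atoms()]
    rmsd_backbone = aligned_rmsd(native, predicted, backbone_keys, correspondence)
    rmsd_pocket = aligned_rmsd(native, predicted, pocket.atom_keys, correspondence)

    nat_l, pred_l, _ = correspondence.resolve(native, predicted, None, which="ligand")
    if len(nat_l) < 3:
        raise DegenerateGeometryError("ligand has fewer than 3 paired heavy atoms")
    _, rmsd_ligand = kabsch_superpose(pred_l, nat_l)

    rmsd_pal = pocket_aligned_ligand_rmsd(native, predicted, pocket, correspondence)
    return PoseMetrics(
        rmsd_backbone=rmsd_backbone,
        rmsd_pocket=rmsd_pocket,
        rmsd_ligand=rmsd_ligand,
        rmsd_pocket_aligned_ligand=rmsd_pal,
        pocket_coverage=correspondence.pocket_coverage(pocket),
        rank=rank,
        method_label=method_label,
    )


def best_of(poses: Sequence[PoseMetrics], reference: str = "pocket_aligned_ligand") -> PoseMetrics:
    """The pose minimising the chosen reference metric; ties go to lower rank."""
    if not poses:
        raise ValueError("empty pose list")
    if reference not in METRIC_NAMES:
        raise ValueError(f"unknown reference {reference!r}; choose from {METRIC_NAMES}")
    return min(poses, key=lambda p: (p.metric(reference), p.rank))
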