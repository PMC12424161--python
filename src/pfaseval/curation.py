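"""Dataset inclusion filters and the release-date train/test split.

Benchmark entries are kept when they describe exactly one protein chain
bound to exactly one PFAS ligand, with more than 50 residues (strictly) and
no nonstandard amino acids.  Entries are then partitioned into a "Before"
set (release date on or before the predictor's training cutoff, default
2021-09-30) and an "After" set (released later), so that performance on
structures the predictor may have seen during training can be compared with
performance on genuinely unseen structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "DatasetEntry",
    "SplitLabel",
    "DEFAULT_CUTOFF",
    "filter_entry",
    "filter_entries",
    "split_by_date",
    "split_label",
    "parse_release_date",
    "load_manifest",
    "load_cf2cf_benchmark",
]

DEFAULT_CUTOFF = date(2021, 9, 30)

BEFORE = "Before"
AFTER = "After"


@dataclass
class DatasetEntry:
    """One benchmark system as listed in a dataset manifest."""

    entry_id: str
    release_date: date | None
    n_protein_chains: int = 1
    n_residues: int = 0
    has_nonstandard_aa: bool = False
    pfas_ligand_ids: list[str] = field(default_factory=list)
    pose_files: dict[str, list[str]] = field(default_factory=dict)
    native_path: str | None = None
    engine_failed: bool = False


@dataclass(frozen=True)
class SplitLabel:
    label: str  # Before | After
    cutoff: date = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.label not in (BEFORE, AFTER):
            raise ValueError(f"split label must be Before/After, got {self.label!r}")


def parse_release_date(value) -> date:
    """Parse ISO-8601 (manifests) or US M/D/YYYY (printed tables) dates."""
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    text = str(value).strip()
    for parser in (date.fromisoformat, lambda s: datetime.strptime(s, "%m/%d/%Y").date()):
        try:
            return parser(text)
        except ValueError:
            continue
    raise ValueError(f"unparseable release date: {value!r}")


def filter_entry(
    entry: DatasetEntry, strict_single_ligand: bool = True
) -> tuple[bool, list[str]]:
    """Apply the inclusion rules; returns (keep, reasons-for-rejection)."""
    reasons = []
    if entry.n_protein_chains != 1:
        reasons.append(f"protein chain count {entry.n_protein_chains} != 1")
    if strict_single_ligand and len(entry.pfas_ligand_ids) != 1:
        reasons.append(f"PFAS ligand count {len(entry.pfas_ligand_ids)} != 1")
    if not entry.pfas_ligand_ids:
        if "PFAS ligand count 0 != 1" not in reasons:
            reasons.append("no PFAS ligand")
    if entry.n_residues <= 50:
        reasons.append(f"residue count not > 50 (got {entry.n_residues})")
    if entry.has_nonstandard_aa:
        reasons.append("contains nonstandard amino acids")
    if entry.engine_failed:
        reasons.append("flagged as failed in a docking engine")
    return (not reasons), reasons


def filter_entries(
    entries: list[DatasetEntry], strict_single_ligand: bool = True
) -> tuple[list[DatasetEntry], list[tuple[DatasetEntry, list[str]]]]:
    kept, rejected = [], []
    for entry in entries:
        keep, reasons = filter_entry(entry, strict_single_ligand)
        (kept if keep else rejected).append(entry if keep else (entry, reasons))
    return kept, rejected


def split_label(release_date: date, cutoff: date = DEFAULT_CUTOFF) -> SplitLabel:
    """Dates on the cutoff day itself count as Before (documented choice)."""
    return SplitLabel(BEFORE if release_date <= cutoff else AFTER, cutoff)


def split_by_date(
    entries: list[DatasetEntry], cutoff: date = DEFAULT_CUTOFF
) -> tuple[list[DatasetEntry], list[DatasetEntry], list[tuple[DatasetEntry, str]]]:
    """Partition entries into (before, after, errors) by release date.

    Entries whose date is missing or unparseable end up in ``errors`` with a
    message; the three lists always partition the input exhaustively.
    """
    before, after, errors = [], [], []
    for entry in entries:
        try:
            if entry.release_date is None:
                raise ValueError("missing release date")
            d = parse_release_date(entry.release_date)
        except ValueError as exc:
            errors.append((entry, str(exc)))
            continue
        (before if split_label(d, cutoff).label == BEFORE else after).append(entry)
    return before, after, errors


# ---------------------------------------------------------------------------
# manifests


def load_manifest(path: str | Path) -> list[DatasetEntry]:
    """Read a dataset manifest (CSV or JSON).

    Required columns/keys: ``entry_id``, ``release_date``; optional:
    ``ligand_id`` (or ``pfas_ligand_ids`` list), ``native_path``,
    ``n_protein_chains``, ``n_residues``, ``has_nonstandard_aa``,
    ``engine_failed`` and one ``poses_<method>`` column per method holding
    ``;``-separated pose paths (JSON may use a ``pose_files`` mapping).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        import json

        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    entries = []
    for row in rows:
        pose_files: dict[str, list[str]] = {}
        if isinstance(row.get("pose_files"), dict):
            pose_files = {k: list(v) for k, v in row["pose_files"].items()}
        else:
            for key, value in row.items():
                if key.startswith("poses_") and isinstance(value, str) and value:
                    pose_files[key[len("poses_"):]] = value.split(";")
        ligands = row.get("pfas_ligand_ids")
        if ligands is None:
            lig = row.get("ligand_id")
            ligands = [lig] if lig else []
        entries.append(
            DatasetEntry(
                entry_id=str(row["entry_id"]),
                release_date=parse_release_date(row["release_date"])
                if row.get("release_date") not in (None, "")
                else None,
                n_protein_chains=int(row.get("n_protein_chains", 1)),
                n_residues=int(row.get("n_residues", 0)),
                has_nonstandard_aa=_as_bool(row.get("has_nonstandard_aa", False)),
                pfas_ligand_ids=list(ligands),
                pose_files=pose_files,
                native_path=row.get("native_path"),
                engine_failed=_as_bool(row.get("engine_failed", False)),
            )
        )
    return entries


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def load_cf2cf_benchmark() -> pd.DataFrame:
    """The bundled worked example: 18 protein-PFAS complexes carrying the
    EPA -CF2-CF- motif, with release dates and the published per-complex
    RMSDs (nm) for two prediction methods under the four references."""
    with resources.files("pfaseval.data").joinpath("cf2cf_benchmark.csv").open() as fh:
        df = pd.read_csv(fh)
    df["release_date"] = df["release_date"].map(parse_release_date)
    return df
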