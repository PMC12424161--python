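"""Success-rate aggregation, bootstrap intervals, group tests, Top-N and
hybrid pose selection, and failure-mode decomposition.

A prediction counts as a *success* when its heavy-atom RMSD under the chosen
alignment reference is at or below a threshold (0.2 nm by default, boundary
inclusive).  Rates are reported in percent with 95% percentile-bootstrap
confidence intervals (10,000 resamples by default), and group differences
are assessed with Welch's unequal-variance t-test applied to the 0/1
success indicators.

Failed pocket-aligned predictions are decomposed, non-exclusively, into
three modes by inspecting the constituent metrics of the same pose:

* ``ligand_structure``  -- the ligand-aligned RMSD also exceeds the threshold
  (the ligand itself was built wrong);
* ``pocket_structure``  -- the pocket RMSD also exceeds the threshold
  (the pocket was built wrong);
* ``orientation``       -- neither constituent exceeds it: ligand and pocket
  are each fine, but the ligand is placed or oriented wrongly in the pocket.

``both`` marks records where ligand and pocket structure both failed.  The
categories deliberately overlap (a record can be both a ligand-structure and
a pocket-structure failure), so mode shares can sum to more than 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pose_metrics import METRIC_NAMES, PoseMetrics

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_RESAMPLES",
    "DEFAULT_SEED",
    "EvaluationTable",
    "SuccessSummary",
    "FailureModes",
    "success_rate",
    "bootstrap_ci",
    "welch_test",
    "significance_stars",
    "topn_success",
    "hybrid_success",
    "classify_failure",
    "failure_mode_shares",
    "aggregate_report",
]

DEFAULT_THRESHOLD = 0.2  # nm
DEFAULT_RESAMPLES = 10_000
DEFAULT_SEED = 20250826


@dataclass(frozen=True)
class SuccessSummary:
    """A success rate (%) with its bootstrap confidence interval."""

    group: tuple
    n: int
    successes: int
    rate: float
    ci_low: float
    ci_high: float
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.rate <= 100):
            raise ValueError("rate must be a percentage in [0, 100]")
        if not (self.ci_low - 1e-9 <= self.rate <= self.ci_high + 1e-9):
            raise ValueError("CI must bracket the rate")
        if self.successes > self.n:
            raise ValueError("successes cannot exceed n")


@dataclass(frozen=True)
class FailureModes:
    orientation: bool
    ligand_structure: bool
    pocket_structure: bool
    both: bool


@dataclass
class EvaluationTable:
    """Tidy per-pose records feeding every aggregation in this module.

    One row per (entry, method, rank) with the four RMSDs, the Before/After
    split label and, optionally, PFAS classification columns.
    """

    frame: pd.DataFrame

    REQUIRED = ("entry_id", "method_label", "rank",
                "rmsd_backbone", "rmsd_pocket", "rmsd_ligand",
                "rmsd_pocket_aligned_ligand")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"evaluation table missing columns: {missing}")
        dup = df.duplicated(["entry_id", "method_label", "rank"])
        if dup.any():
            raise ValueError("(entry_id, method_label, rank) must be unique")
        for (_e, _m), ranks in df.groupby(["entry_id", "method_label"])["rank"]:
            expected = list(range(1, len(ranks) + 1))
            if sorted(ranks) != expected:
                raise ValueError(
                    f"ranks for {(_e, _m)} must be contiguous from 1, got {sorted(ranks)}"
                )

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "EvaluationTable":
        return cls(pd.DataFrame(list(records)))

    def methods(self) -> list[str]:
        return sorted(self.frame["method_label"].unique())


# ---------------------------------------------------------------------------
# core statistics


def success_rate(values: Sequence[float], threshold: float = DEFAULT_THRESHOLD) -> float:
    """Percentage of RMSD values at or below the threshold (inclusive)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("success rate of an empty sample is undefined")
    return float(100.0 * np.count_nonzero(arr <= threshold) / arr.size)


def bootstrap_ci(
    outcomes: Sequence[int] | np.ndarray,
    n_resamples: int = DEFAULT_RESAMPLES,
    level: float = 0.95,
    seed: int = DEFAULT_SEED,
    method: str = "percentile",
) -> tuple[float, float]:
    """Percentile bootstrap CI (in %) for the mean of a 0/1 outcome vector.

    For binary data, resampling n observations with replacement and averaging
    is distributionally identical to drawing Binomial(n, p-hat)/n, so that
    shortcut is used; non-binary vectors fall back to index resampling.
    Deterministic for a fixed seed.
    """
    arr = np.asarray(outcomes, dtype=float)
    if arr.size == 0:
        raise ValueError("empty outcome vector")
    if method != "percentile":
        raise ValueError(f"unsupported bootstrap method {method!r}")
    rng = np.random.default_rng(seed)
    n = arr.size
    if np.isin(arr, (0.0, 1.0)).all():
        p_hat = arr.mean()
        means = rng.binomial(n, p_hat, size=n_resamples) / n
    else:
        idx = rng.integers(0, n, size=(n_resamples, n))
        means = arr[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(100.0 * low), float(100.0 * high)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, str]:
    """Welch's unequal-variance two-sample t-test: (t, p, stars)."""
    x = np.asarray(a, float)
    y = np.asarray(b, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), significance_stars(float(p))


# ---------------------------------------------------------------------------
# selection strategies


def _summary(
    outcomes: np.ndarray,
    group: tuple,
    seed: int,
    n_resamples: int = DEFAULT_RESAMPLES,
) -> SuccessSummary:
    n = outcomes.size
    successes = int(outcomes.sum())
    rate = 100.0 * successes / n
    low, high = bootstrap_ci(outcomes, n_resamples=n_resamples, seed=seed)
    # percentile CIs of a proportion always bracket the point estimate
    low, high = min(low, rate), max(high, rate)
    return SuccessSummary(
        group=group, n=n, successes=successes, rate=rate,
        ci_low=low, ci_high=high, seed=seed,
    )


def per_entry_min(
    table: EvaluationTable,
    method: str,
    n: int,
    reference: str = "pocket_aligned_ligand",
) -> pd.Series:
    """Per entry: the minimum of the reference metric over ranks 1..n.

    ``n`` larger than the number of available poses simply uses them all.
    """
    col = f"rmsd_{reference}"
    df = table.frame[table.frame["method_label"] == method]
    sub = df[df["rank"] <= n]
    if sub.empty:
        return pd.Series(dtype=float)
    return sub.groupby("entry_id")[col].min()


def topn_success(
    table: EvaluationTable,
    n: int,
    reference: str = "pocket_aligned_ligand",
    method: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = DEFAULT_SEED,
    n_resamples: int = DEFAULT_RESAMPLES,
) -> SuccessSummary:
    """Success rate when each entry is scored by its best pose among the
    top-n ranked predictions of one method."""
    if method is None:
        methods = table.methods()
        if len(methods) != 1:
            raise ValueError(f"table holds several methods {methods}; pass method=")
        method = methods[0]
    minima = per_entry_min(table, method, n, reference)
    if minima.empty:
        raise ValueError(f"no poses for method {method!r}")
    outcomes = (minima <= threshold).to_numpy(dtype=float)
    return _summary(outcomes, (method, f"top{n}", reference), seed, n_resamples)


def hybrid_success(
    table: EvaluationTable,
    methods: Sequence[str],
    n: int | dict[str, int] = 5,
    reference: str = "pocket_aligned_ligand",
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = DEFAULT_SEED,
    n_resamples: int = DEFAULT_RESAMPLES,
) -> SuccessSummary:
    """Success rate over the union of each method's top-n candidate poses.

    Entries missing poses for any listed method are excluded with a warning
    (their denominator would not be comparable across methods).
    """
    if not methods:
        raise ValueError("need at least one method")
    n_per = n if isinstance(n, dict) else {m: n for m in methods}
    minima = []
    for m in methods:
        s = per_entry_min(table, m, n_per[m], reference)
        if s.empty:
            raise ValueError(f"no poses for method {m!r}")
        minima.append(s)
    combined = pd.concat(minima, axis=1, join="outer")
    incomplete = combined.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} entries lack poses for some of {list(methods)}; excluded",
            stacklevel=2,
        )
        combined = combined[~incomplete]
    if combined.empty:
        raise ValueError("no entry has poses for every requested method")
    best = combined.min(axis=1)
    outcomes = (best <= threshold).to_numpy(dtype=float)
    label = "+".join(f"{m}-top{n_per[m]}" for m in methods)
    return _summary(outcomes, (label, "hybrid", reference), seed, n_resamples)


# ---------------------------------------------------------------------------
# failure modes


def classify_failure(
    m: PoseMetrics | dict, threshold: float = DEFAULT_THRESHOLD
) -> FailureModes | None:
    """Decompose a failed pocket-aligned prediction into modes; ``None`` when
    the pose is a success under the pocket-aligned reference."""
    get = (lambda k: getattr(m, k)) if isinstance(m, PoseMetrics) else m.__getitem__
    if get("rmsd_pocket_aligned_ligand") <= threshold:
        return None
    ligand_bad = get("rmsd_ligand") > threshold
    pocket_bad = get("rmsd_pocket") > threshold
    return FailureModes(
        orientation=not ligand_bad and not pocket_bad,
        ligand_structure=ligand_bad,
        pocket_structure=pocket_bad,
        both=ligand_bad and pocket_bad,
    )


def failure_mode_shares(
    table: EvaluationTable,
    method: str | None = None,
    rank: int = 1,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Shares (%) of each failure mode among failed rank-``rank`` poses,
    with bootstrap CIs.  Shares can exceed 100% in total because ligand- and
    pocket-structure failures are not mutually exclusive."""
    df = table.frame
    if method is not None:
        df = df[df["method_label"] == method]
    df = df[df["rank"] == rank]
    failed = df[df["rmsd_pocket_aligned_ligand"] > threshold]
    if failed.empty:
        return pd.DataFrame(
            columns=["mode", "n_failed", "count", "share", "ci_low", "ci_high"]
        )
    modes = [classify_failure(row, threshold) for row in failed.to_dict("records")]
    rows = []
    for name in ("orientation", "ligand_structure", "pocket_structure", "both"):
        flags = np.array([getattr(fm, name) for fm in modes], dtype=float)
        low, high = bootstrap_ci(flags, seed=seed)
        rows.append(
            {
                "mode": name,
                "n_failed": len(modes),
                "count": int(flags.sum()),
                "share": 100.0 * flags.mean(),
                "ci_low": low,
                "ci_high": high,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full report


def aggregate_report(
    table: EvaluationTable,
    group_by: Sequence[str] = ("split",),
    references: Sequence[str] = METRIC_NAMES,
    strategies: Sequence[int] = (1, 5),
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = DEFAULT_SEED,
    n_resamples: int = DEFAULT_RESAMPLES,
) -> pd.DataFrame:
    """One success summary per (method x group x reference x Top-n strategy).

    ``group_by`` names columns of the table (e.g. ``split``,
    ``charge_category``); groups with no entries are skipped with a warning.
    Deterministic for a fixed seed.
    """
    df = table.frame
    for col in group_by:
        if col not in df.columns:
            raise ValueError(f"grouping column {col!r} not in table")
    rows = []
    groups = df.groupby(list(group_by)) if group_by else [((), df)]
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        subtable = EvaluationTable(sub.reset_index(drop=True))
        for method in subtable.methods():
            for reference in references:
                for n in strategies:
                    try:
                        s = topn_success(
                            subtable, n, reference, method=method,
                            threshold=threshold, seed=seed, n_resamples=n_resamples,
                        )
                    except ValueError:
                        warnings.warn(
                            f"group {key} / {method}: no poses, skipped", stacklevel=2
                        )
                        continue
                    rows.append(
                        {
                            **dict(zip(group_by, key)),
                            "method_label": method,
                            "reference": reference,
                            "strategy": f"top{n}",
                            "n": s.n,
                            "successes": s.successes,
                            "rate": s.rate,
                            "ci_low": s.ci_low,
                            "ci_high": s.ci_high,
                            "seed": s.seed,
                        }
                    )
    return pd.DataFrame(rows)


def compare_splits(
    table: EvaluationTable,
    reference: str = "pocket_aligned_ligand",
    n: int = 1,
    threshold: float = DEFAULT_THRESHOLD,
    split_column: str = "split",
) -> pd.DataFrame:
    """Welch comparisons of Before-vs-After success indicators, per method."""
    df = table.frame
    if split_column not in df.columns:
        raise ValueError(f"table has no {split_column!r} column")
    rows = []
    for method in table.methods():
        indicators = {}
        for split, sub in df[df["method_label"] == method].groupby(split_column):
            subtable = EvaluationTable(sub.reset_index(drop=True))
            minima = per_entry_min(subtable, method, n, reference)
            indicators[split] = (minima <= threshold).to_numpy(dtype=float)
        if len(indicators) != 2:
            warnings.warn(f"{method}: need exactly two splits, got {list(indicators)}")
            continue
        (la, a), (lb, b) = sorted(indicators.items())
        try:
            t, p, star = welch_test(a, b)
        except ValueError as exc:  # degenerate (e.g. all-success) groups
            warnings.warn(f"{method}: Welch comparison degenerate: {exc}")
            t, p, star = float("nan"), float("nan"), ""
        rows.append(
            {
                "method_label": method,
                "reference": reference,
                "strategy": f"top{n}",
                "group_a": la, "rate_a": 100 * a.mean(), "n_a": a.size,
                "group_b": lb, "rate_b": 100 * b.mean(), "n_b": b.size,
                "t": t, "p": p, "stars": star,
            }
        )
    return pd.DataFrame(rows)
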