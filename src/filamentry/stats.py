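"""Nonparametric inference chain for per-colony f-measures.

The chain applied to each strain is: robust outlier removal with the
Iglewicz–Hoaglin modified z-score, a tie-corrected Kruskal–Wallis test
across the dose groups, and — when that test rejects — Dunn's pairwise
rank comparisons with a Bonferroni correction.  Group summaries (mean ± SD,
with a non-determined flag for strains that never filament) and signed
relative changes between group means complete the reported tables.

Rank-based tests are used because per-colony f-measure distributions are
right-skewed with unequal spread across dose groups, so a normal-theory
ANOVA would be miscalibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateScaleWarning, InferenceError, UndefinedChangeError

__all__ = [
    "OutlierReport",
    "KruskalWallisResult",
    "DunnResult",
    "modified_z_outliers",
    "filter_outliers",
    "kruskal_wallis",
    "dunn_bonferroni",
    "summarize_groups",
    "relative_change",
]

MODIFIED_Z_THRESHOLD = 3.5  # conventional Iglewicz–Hoaglin cut-off
ND_LABEL = "N.D."
FILAMENTOUS_LABEL = "filamentous"


@dataclass
class OutlierReport:
    """Per-value modified z-scores and outlier flags for one group of values.

    Removal is non-destructive: the report keeps the original values, their
    scores and a boolean flag per value; callers drop flagged entries
    themselves.
    """

    values: np.ndarray
    modified_z: np.ndarray
    flagged: np.ndarray
    threshold: float
    median: float
    mad: float

    @property
    def kept(self) -> np.ndarray:
        return self.values[~self.flagged]


def modified_z_outliers(
    values: Sequence[float], threshold: float = MODIFIED_Z_THRESHOLD
) -> OutlierReport:
    """Flag outliers by the modified z-score M_i = 0.6745·(x_i − med) / MAD.

    MAD is the median absolute deviation from the median.  Values with
    |M_i| > ``threshold`` (3.5 by convention) are flagged in a single pass.
    A zero MAD means the scale is degenerate: nothing is flagged and a
    :class:`DegenerateScaleWarning` is emitted.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InferenceError("modified z-score needs at least 3 values")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        warnings.warn(
            "MAD is zero; modified z-scores are undefined and no outliers "
            "are flagged",
            DegenerateScaleWarning,
            stacklevel=2,
        )
        m = np.zeros_like(x)
        flagged = np.zeros(x.shape, dtype=bool)
    else:
        m = 0.6745 * (x - med) / mad
        flagged = np.abs(m) > threshold
    return OutlierReport(
        values=x, modified_z=m, flagged=flagged, threshold=threshold,
        median=med, mad=mad,
    )


def filter_outliers(
    table: pd.DataFrame,
    threshold: float = MODIFIED_Z_THRESHOLD,
    by: Sequence[str] = ("strain",),
    value_col: str = "f_measure",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the modified z-score filter within each group of a long table.

    The default scope is per strain, pooling the dose groups: a filter
    that ignores the dose labels leaves the surviving values exchangeable
    across doses under the null hypothesis, so the downstream rank test
    keeps its nominal level.  Filtering within strain × dose instead
    (``by=("strain", "dose_uM")``) shrinks the within-group spread in a
    data-dependent way and makes the chain anti-conservative.

    Returns ``(kept_rows, report)`` where ``report`` has one row per input
    value with its group keys, score and flag.  Groups with fewer than 3
    values are passed through unfiltered (scores NaN).
    """
    reports = []
    for keys, sub in table.groupby(list(by), sort=False):
        vals = sub[value_col].to_numpy(dtype=float)
        if vals.size < 3:
            m = np.full(vals.shape, np.nan)
            flagged = np.zeros(vals.shape, dtype=bool)
        else:
            rep = modified_z_outliers(vals, threshold)
            m, flagged = rep.modified_z, rep.flagged
        part = sub.copy()
        part["modified_z"] = m
        part["outlier"] = flagged
        reports.append(part)
    report = pd.concat(reports) if reports else table.assign(
        modified_z=np.nan, outlier=False
    )
    report = report.loc[table.index]
    kept = report.loc[~report["outlier"], table.columns.tolist()]
    return kept, report


@dataclass(frozen=True)
class KruskalWallisResult:
    """Tie-corrected Kruskal–Wallis H with its chi-square p-value."""

    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]
    strain: str | None = None


def _check_groups(groups: Sequence[Sequence[float]], labels=None) -> list[np.ndarray]:
    if len(groups) < 2:
        raise InferenceError("need at least 2 groups")
    arrays = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size == 0:
            name = labels[i] if labels is not None else f"group {i}"
            raise InferenceError(f"group {name!r} is empty")
        arrays.append(a)
    return arrays


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    strain: str | None = None,
) -> KruskalWallisResult:
    """Kruskal–Wallis rank test across k groups (mid-ranks, tie-corrected).

    p is taken from the upper tail of the chi-square distribution with
    df = k − 1.  A pooled sample with no variation at all gives H = 0, p = 1.
    """
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:  # scipy rejects all-identical data
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*arrays)
    return KruskalWallisResult(
        H=float(H),
        df=len(arrays) - 1,
        p=float(p),
        group_sizes=tuple(a.size for a in arrays),
        strain=strain,
    )


@dataclass(frozen=True)
class DunnResult:
    """One pairwise Dunn comparison with its Bonferroni-adjusted p-value."""

    pair: tuple[object, object]
    z: float
    p_raw: float
    p_adj: float
    strain: str | None = None


def dunn_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Sequence[object] | None = None,
    strain: str | None = None,
) -> list[DunnResult]:
    """Dunn's post-hoc z tests on joint mid-ranks, Bonferroni-corrected.

    For groups i, j with mean joint ranks R̄ and sizes n::

        z = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)]

    where ``T = Σ(t³ − t)`` over tied-value multiplicities.  Two-sided p
    from the standard normal; ``p_adj = min(1, m·p_raw)`` with
    m = k(k−1)/2 comparisons.
    """
    arrays = _check_groups(groups, labels)
    if labels is None:
        labels = list(range(len(arrays)))
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + a.size].mean()))
        sizes.append(a.size)
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    m = len(arrays) * (len(arrays) - 1) // 2

    results = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if denom == 0.0 else (mean_ranks[i] - mean_ranks[j]) / denom
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            results.append(
                DunnResult(
                    pair=(labels[i], labels[j]),
                    z=float(z),
                    p_raw=p_raw,
                    p_adj=min(1.0, m * p_raw),
                    strain=strain,
                )
            )
    return results


def summarize_groups(
    table: pd.DataFrame,
    nd_epsilon: float = 0.0,
    value_col: str = "f_measure",
) -> pd.DataFrame:
    """Per strain × dose n/mean/SD with a strain-level filamentation call.

    A strain is classified ``N.D.`` (non-determined / no filamentation)
    when every colony at every dose measures below ``nd_epsilon``; such
    strains are excluded from inference downstream.  SD is the sample
    (ddof=1) standard deviation, 0 for singleton groups.
    """
    if table.empty:
        raise InferenceError("cannot summarize an empty table")
    rows = []
    for (strain, dose), sub in table.groupby(["strain", "dose_uM"], sort=True):
        v = sub[value_col].to_numpy(dtype=float)
        rows.append(
            {
                "strain": strain,
                "dose_uM": dose,
                "n": v.size,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    nd_strains = {
        strain
        for strain, sub in table.groupby("strain")
        if (sub[value_col] < nd_epsilon).all()
    }
    out["classification"] = [
        ND_LABEL if s in nd_strains else FILAMENTOUS_LABEL for s in out["strain"]
    ]
    return out


def relative_change(mean_a: float, mean_b: float) -> float:
    """Signed percent change from baseline mean_a to mean_b.

    ``100 · (mean_b − mean_a) / mean_a``; undefined for a non-positive
    baseline.
    """
    if mean_a <= 0:
        raise UndefinedChangeError(
            f"relative change undefined for baseline mean {mean_a}"
        )
    return 100.0 * (mean_b - mean_a) / mean_a
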