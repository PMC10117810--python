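"""Published reference tables for 16 commercial brewing strains.

These are the reported whole-colony filamentation results of a published
screen of commercial *S. cerevisiae* brewing strains grown on
nitrogen-limiting SLAD agar with 0, 100 or 200 µM exogenous
2-phenylethanol: per-group mean ± SD f-measures, per-strain Kruskal–Wallis
statistics, Dunn–Bonferroni pairwise p-values, and the tabulated relative
changes between group means.  The underlying per-colony measurements and
raw micrographs were not deposited, so these summaries are the available
ground for cross-checks: the relative-change table can be recomputed from
the summary means, and the cohort generator can be pointed at the
mean/SD rows to simulate cohorts with matching moments.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_reference_summaries",
    "load_reference_kruskal",
    "load_reference_dunn",
    "load_reference_relative_changes",
    "significant_pairs",
    "DOSES_UM",
]

DOSES_UM = (0.0, 100.0, 200.0)

# strain: (mean, sd) at 0, 100, 200 uM
_SUMMARIES = {
    "YMD4519": [(0.324, 0.149), (0.315, 0.398), (0.318, 0.150)],
    "YMD4521": [(0.370, 0.141), (0.427, 0.245), (0.289, 0.145)],
    "YMD4531": [(0.364, 0.109), (0.465, 0.271), (0.381, 0.178)],
    "YMD4537": [(0.533, 0.138), (0.710, 0.376), (0.545, 0.163)],
    "YMD4538": [(0.689, 0.243), (1.472, 0.836), (1.074, 0.257)],
    "YMD4541": [(0.228, 0.108), (0.257, 0.079), (0.197, 0.056)],
    "YMD4545": [(0.965, 0.544), (0.220, 0.090), (0.213, 0.048)],
    "YMD4548": [(0.426, 0.978), (0.624, 1.545), (0.283, 0.598)],
    "YMD4552": [(0.310, 0.199), (0.288, 0.137), (0.199, 0.054)],
    "YMD4553": [(0.252, 0.142), (0.433, 0.493), (0.794, 1.421)],
}

# strain: (chi-square statistic, p); strains that never filamented are N.D.
_KRUSKAL = {
    "YMD4519": (10.751, 0.005),
    "YMD4521": (7.031, 0.030),
    "YMD4525": None,
    "YMD4529": None,
    "YMD4531": (2.044, 0.360),
    "YMD4533": None,
    "YMD4534": None,
    "YMD4537": (13.661, 0.001),
    "YMD4538": (34.149, 0.000),
    "YMD4541": (11.820, 0.003),
    "YMD4542": None,
    "YMD4544": None,
    "YMD4545": (53.449, 0.000),
    "YMD4548": (3.817, 0.148),
    "YMD4552": (13.203, 0.001),
    "YMD4553": (7.480, 0.024),
}

# strain: Bonferroni-adjusted Dunn p for (0/100, 0/200, 100/200)
_DUNN = {
    "YMD4519": (0.018, 1.0, 0.010),
    "YMD4521": (1.0, 0.106, 0.043),
    "YMD4537": (0.003, 1.0, 0.007),
    "YMD4538": (0.000, 0.000, 1.0),
    "YMD4541": (0.043, 1.0, 0.003),
    "YMD4545": (0.000, 0.000, 1.0),
    "YMD4552": (1.0, 0.013, 0.002),
    "YMD4553": (0.023, 0.198, 1.0),
}

# strain: tabulated percent change for (0->100 uM, 100->200 uM); None = not reported
_RELATIVE_CHANGES = {
    "YMD4519": (-2.63, 0.74),
    "YMD4521": (None, -32.37),
    "YMD4537": (33.17, -23.17),
    "YMD4538": (113.60, None),
    "YMD4541": (12.47, -23.36),
    "YMD4545": (-77.16, None),
    "YMD4552": (None, -30.90),
    "YMD4553": (71.60, None),
}


def load_reference_summaries() -> pd.DataFrame:
    """Mean ± SD f-measure per strain × dose for the filamentous strains."""
    rows = [
        {"strain": s, "dose_uM": d, "mean": m, "sd": sd}
        for s, entries in _SUMMARIES.items()
        for d, (m, sd) in zip(DOSES_UM, entries)
    ]
    return pd.DataFrame(rows)


def load_reference_kruskal() -> pd.DataFrame:
    """Per-strain chi-square statistic and p; N.D. strains carry NaN."""
    rows = []
    for s, entry in _KRUSKAL.items():
        if entry is None:
            rows.append({"strain": s, "chi2": float("nan"), "p": float("nan"),
                         "classification": "N.D."})
        else:
            rows.append({"strain": s, "chi2": entry[0], "p": entry[1],
                         "classification": "filamentous"})
    return pd.DataFrame(rows)


def load_reference_dunn() -> pd.DataFrame:
    """Bonferroni-adjusted pairwise p-values for the tested strains."""
    pairs = [(0.0, 100.0), (0.0, 200.0), (100.0, 200.0)]
    rows = [
        {"strain": s, "dose_a": a, "dose_b": b, "p_adj": p}
        for s, ps in _DUNN.items()
        for (a, b), p in zip(pairs, ps)
    ]
    return pd.DataFrame(rows)


def load_reference_relative_changes() -> pd.DataFrame:
    """Tabulated percent changes of mean f-measure; unreported cells omitted."""
    rows = []
    for s, (c01, c12) in _RELATIVE_CHANGES.items():
        if c01 is not None:
            rows.append(
                {"strain": s, "dose_a": 0.0, "dose_b": 100.0, "percent_change": c01}
            )
        if c12 is not None:
            rows.append(
                {"strain": s, "dose_a": 100.0, "dose_b": 200.0, "percent_change": c12}
            )
    return pd.DataFrame(rows)


def significant_pairs(alpha: float = 0.05) -> pd.DataFrame:
    """Dose pairs reported significant in the published post-hoc tests."""
    d = load_reference_dunn()
    return d.loc[d["p_adj"] < alpha, ["strain", "dose_a", "dose_b"]].reset_index(
        drop=True
    )
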