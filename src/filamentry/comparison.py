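"""Strain-by-dose comparison model over per-colony f-measure tables.

:class:`FilamentationComparison` is the modelling entry point: construct it
from a long-format table of per-colony f-measures (columns ``strain``,
``dose_uM``, ``colony_id``, ``f_measure``) and call :meth:`fit`.  Fitting
runs the full inference chain —

* modified z-score outlier removal within each strain × dose group,
* N.D. classification (strains with no filamentation at any dose are
  summarized but excluded from testing),
* a Kruskal–Wallis test per strain across dose groups,
* Dunn–Bonferroni pairwise dose comparisons for strains whose
  Kruskal–Wallis test rejects at ``alpha``,
* signed relative changes of group means for the significant pairs —

and returns a :class:`FilamentationResults` carrying the four result
tables and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as fstats
from .exceptions import InferenceError

__all__ = ["FilamentationComparison", "FilamentationResults"]


class FilamentationComparison:
    """Nonparametric dose-response comparison of whole-colony filamentation.

    Parameters
    ----------
    table
        Long-format per-colony records with at least ``strain``,
        ``dose_uM`` and ``f_measure`` columns (``colony_id`` optional but
        recommended; duplicates of (strain, dose_uM, colony_id) are
        rejected).
    alpha
        Significance level gating the post-hoc stage (default 0.05).
    outlier_threshold
        Modified z-score cut-off (default 3.5); single-pass removal.
    outlier_groupby
        Keys within which the outlier filter operates; default
        ``("strain",)`` (all doses of a strain pooled), which leaves the
        surviving values exchangeable across doses under the null and so
        preserves the nominal level of the rank test.  Use
        ``("strain", "dose_uM")`` to filter each dose group separately —
        stricter on within-group outliers but anti-conservative.
    nd_epsilon
        A strain whose every colony at every dose falls below this value is
        classified N.D. and excluded from inference.  Zero by default;
        image-driven callers use a small positive fraction of A_inner.
    summaries_on
        ``"filtered"`` (default) computes group means/SDs after outlier
        removal, ``"raw"`` before.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        *,
        alpha: float = 0.05,
        outlier_threshold: float = fstats.MODIFIED_Z_THRESHOLD,
        outlier_groupby: Sequence[str] = ("strain",),
        nd_epsilon: float = 0.0,
        summaries_on: str = "filtered",
        value_col: str = "f_measure",
    ) -> None:
        required = {"strain", "dose_uM", value_col}
        missing = required - set(table.columns)
        if missing:
            raise InferenceError(f"table lacks columns {sorted(missing)}")
        if table.empty:
            raise InferenceError("table is empty")
        if (table[value_col] < 0).any():
            raise InferenceError("f-measures must be non-negative")
        if "colony_id" in table.columns:
            dup = table.duplicated(["strain", "dose_uM", "colony_id"])
            if dup.any():
                raise InferenceError("duplicate (strain, dose, colony_id) rows")
        if summaries_on not in ("filtered", "raw"):
            raise InferenceError("summaries_on must be 'filtered' or 'raw'")
        self.table = table.reset_index(drop=True)
        self.alpha = float(alpha)
        self.outlier_threshold = float(outlier_threshold)
        self.outlier_groupby = tuple(outlier_groupby)
        self.nd_epsilon = float(nd_epsilon)
        self.summaries_on = summaries_on
        self.value_col = value_col

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "FilamentationComparison":
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FilamentationComparison":
        return cls(pd.read_csv(path), **kwargs)

    # -- estimation --------------------------------------------------------
    def fit(self) -> "FilamentationResults":
        kept, outlier_report = fstats.filter_outliers(
            self.table,
            threshold=self.outlier_threshold,
            by=self.outlier_groupby,
            value_col=self.value_col,
        )
        basis = kept if self.summaries_on == "filtered" else self.table
        summaries = fstats.summarize_groups(
            basis, nd_epsilon=self.nd_epsilon, value_col=self.value_col
        )
        nd_strains = set(
            summaries.loc[summaries["classification"] == fstats.ND_LABEL, "strain"]
        )

        kw_rows, dunn_rows, change_rows = [], [], []
        for strain, sub in kept.groupby("strain", sort=True):
            if strain in nd_strains:
                continue
            doses = sorted(sub["dose_uM"].unique())
            groups = [
                sub.loc[sub["dose_uM"] == d, self.value_col].to_numpy() for d in doses
            ]
            if len(groups) < 2 or any(g.size < 2 for g in groups):
                continue  # not comparable after filtering
            kw = fstats.kruskal_wallis(groups, strain=strain)
            kw_rows.append(
                {
                    "strain": strain,
                    "H": kw.H,
                    "df": kw.df,
                    "p": kw.p,
                    "significant": kw.p < self.alpha,
                }
            )
            if kw.p >= self.alpha:
                continue
            means = {d: float(g.mean()) for d, g in zip(doses, groups)}
            for res in fstats.dunn_bonferroni(groups, labels=doses, strain=strain):
                a, b = res.pair
                dunn_rows.append(
                    {
                        "strain": strain,
                        "dose_a": a,
                        "dose_b": b,
                        "z": res.z,
                        "p_raw": res.p_raw,
                        "p_adj": res.p_adj,
                        "significant": res.p_adj < self.alpha,
                    }
                )
                if res.p_adj < self.alpha and means[a] > 0:
                    change_rows.append(
                        {
                            "strain": strain,
                            "dose_a": a,
                            "dose_b": b,
                            "percent_change": fstats.relative_change(
                                means[a], means[b]
                            ),
                        }
                    )

        return FilamentationResults(
            model=self,
            table_filtered=kept.reset_index(drop=True),
            outliers=outlier_report.reset_index(drop=True),
            group_summaries=summaries,
            kruskal=pd.DataFrame(
                kw_rows, columns=["strain", "H", "df", "p", "significant"]
            ),
            dunn=pd.DataFrame(
                dunn_rows,
                columns=[
                    "strain", "dose_a", "dose_b", "z", "p_raw", "p_adj", "significant",
                ],
            ),
            relative_changes=pd.DataFrame(
                change_rows, columns=["strain", "dose_a", "dose_b", "percent_change"]
            ),
        )


@dataclass
class FilamentationResults:
    """Fitted tables from a :class:`FilamentationComparison`.

    Attributes mirror the reported tables: per-strain Kruskal–Wallis
    results (``kruskal``), pairwise Dunn–Bonferroni tests (``dunn``),
    relative mean changes for significant pairs (``relative_changes``) and
    per-group summaries with the N.D. classification (``group_summaries``).
    ``outliers`` holds the full modified z-score report.
    """

    model: FilamentationComparison
    table_filtered: pd.DataFrame
    outliers: pd.DataFrame
    group_summaries: pd.DataFrame
    kruskal: pd.DataFrame
    dunn: pd.DataFrame
    relative_changes: pd.DataFrame
    _extra: dict = field(default_factory=dict)

    @property
    def n_outliers_removed(self) -> int:
        return int(self.outliers["outlier"].sum())

    @property
    def significant_strains(self) -> list:
        if self.kruskal.empty:
            return []
        return self.kruskal.loc[self.kruskal["significant"], "strain"].tolist()

    def summary(self) -> str:
        """Human-readable account of the fitted comparison."""
        lines = [
            "Whole-colony filamentation dose-response comparison",
            "=" * 55,
            f"colonies: {len(self.model.table)}  "
            f"(outliers removed: {self.n_outliers_removed}, "
            f"|modified z| > {self.model.outlier_threshold:g})",
            f"alpha: {self.model.alpha:g}   "
            f"N.D. strains: "
            f"{sorted(set(self.group_summaries.loc[self.group_summaries['classification'] == fstats.ND_LABEL, 'strain']))}",
            "",
            "Group summaries (mean ± SD f-measure)",
            "-" * 55,
            self.group_summaries.to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            "Kruskal–Wallis per strain (df = k − 1)",
            "-" * 55,
        ]
        if self.kruskal.empty:
            lines.append("(no testable strains)")
        else:
            lines.append(
                self.kruskal.to_string(index=False, float_format=lambda v: f"{v:.4f}")
            )
        if not self.dunn.empty:
            lines += [
                "",
                "Dunn pairwise tests, Bonferroni-adjusted",
                "-" * 55,
                self.dunn.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            ]
        if not self.relative_changes.empty:
            lines += [
                "",
                "Relative change of mean f-measure (significant pairs)",
                "-" * 55,
                self.relative_changes.to_string(
                    index=False, float_format=lambda v: f"{v:.2f}"
                ),
            ]
        return "\n".join(lines)

    def plot_groups(self, ax=None):
        """Strip/box plot of f-measures by strain and dose (QC display)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        tbl = self.table_filtered
        strains = sorted(tbl["strain"].unique())
        doses = sorted(tbl["dose_uM"].unique())
        width = 0.8 / max(len(doses), 1)
        for di, dose in enumerate(doses):
            xs, ys = [], []
            for si, strain in enumerate(strains):
                vals = tbl.loc[
                    (tbl["strain"] == strain) & (tbl["dose_uM"] == dose),
                    self.model.value_col,
                ]
                xs.extend(np.full(len(vals), si + di * width))
                ys.extend(vals)
            ax.plot(xs, ys, ".", alpha=0.6, label=f"{dose:g} uM")
        ax.set_xticks(np.arange(len(strains)) + 0.4 - width / 2)
        ax.set_xticklabels(strains, rotation=45, ha="right")
        ax.set_ylabel("f-measure")
        ax.legend(title="2-PE dose")
        return ax

    def to_csvs(self, out_dir) -> dict[str, str]:
        """Write the four result tables as CSVs; returns name → path."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("kruskal", self.kruskal),
            ("dunn", self.dunn),
            ("relative_changes", self.relative_changes),
            ("group_summaries", self.group_summaries),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = str(p)
        return paths
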