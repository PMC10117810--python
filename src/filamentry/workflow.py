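"""End-to-end orchestration: images → f-measures → statistics → reports.

:func:`run_assay` drives an :class:`ExperimentManifest` (image paths with
strain/dose/replicate annotations) through the imaging pipeline, fits the
:class:`~filamentry.comparison.FilamentationComparison` model on the
resulting per-colony table, and returns a :class:`ReportBundle` whose CSVs
are byte-reproducible for a fixed manifest and configuration.

:func:`reproduce_printed_tables` recomputes a relative-change table from
published group means for a designated set of dose pairs — the cross-check
available when only summary tables, not raw colonies, were published.

:func:`simulate_assay_table` generates a fully synthetic assay (colony
images rendered and measured on the fly) and is the basis of the null and
power simulations in the test-suite and acceptance harness.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparison import FilamentationComparison, FilamentationResults
from .exceptions import InputError, RunError
from .imaging import PreprocessConfig, measure_image, read_image
from .stats import relative_change
from .synthetic import SyntheticColonySpec, generate_colony_image

__all__ = [
    "ExperimentManifest",
    "ReportBundle",
    "run_assay",
    "reproduce_printed_tables",
    "measure_manifest",
    "simulate_assay_table",
    "GAP_MARKER",
]

GAP_MARKER = "-"  # printed for pairs with no reportable change


@dataclass
class ExperimentManifest:
    """Image inventory for one assay: path, strain, dose and replicate."""

    table: pd.DataFrame
    config: PreprocessConfig = field(default_factory=PreprocessConfig)
    rng_seed: int = 0

    REQUIRED = ("image_path", "strain", "dose_uM", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise InputError(f"manifest lacks columns {sorted(missing)}")
        if self.table.empty:
            raise RunError("manifest is empty")
        if self.table["image_path"].duplicated().any():
            raise InputError("manifest image paths must be unique")

    @classmethod
    def from_csv(cls, path, config: PreprocessConfig | None = None, rng_seed: int = 0):
        return cls(
            table=pd.read_csv(path),
            config=config or PreprocessConfig(),
            rng_seed=rng_seed,
        )

    def validate_paths(self) -> None:
        missing = [p for p in self.table["image_path"] if not Path(p).exists()]
        if missing:
            raise InputError(f"{len(missing)} manifest images missing, e.g. {missing[0]}")


@dataclass
class ReportBundle:
    """Everything a run produces: per-colony table, result tables, log."""

    per_colony: pd.DataFrame
    results: FilamentationResults
    failures: list[dict]
    log: dict

    def write(self, out_dir) -> dict[str, str]:
        """Write per-colony CSV, the four result tables and the run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = out / "per_colony.csv"
        self.per_colony.to_csv(p, index=False, float_format="%.10g")
        paths["per_colony"] = str(p)
        paths.update(self.results.to_csvs(out))
        logp = out / "run_log.json"
        logp.write_text(json.dumps(self.log, indent=2, sort_keys=True))
        paths["run_log"] = str(logp)
        return paths


def _config_hash(config: PreprocessConfig) -> str:
    blob = json.dumps(
        {k: list(v) if isinstance(v, tuple) else v for k, v in vars(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def measure_manifest(
    manifest: ExperimentManifest,
    pixel_size_um: float | None = None,
    max_failure_fraction: float = 0.2,
) -> tuple[pd.DataFrame, list[dict]]:
    """Measure every manifest image; failures are logged and skipped.

    Raises :class:`RunError` when more than ``max_failure_fraction`` of the
    images fail to segment.
    """
    manifest.validate_paths()
    records, failures = [], []
    for _, row in manifest.table.iterrows():
        try:
            img = read_image(row["image_path"], pixel_size_um=pixel_size_um)
            res = measure_image(img, manifest.config, keep_qc=False)
        except Exception as exc:  # noqa: BLE001 - per-image isolation is the point
            failures.append({"image_path": row["image_path"], "error": str(exc)})
            continue
        records.append(
            {
                "strain": row["strain"],
                "dose_uM": float(row["dose_uM"]),
                "colony_id": str(Path(row["image_path"]).stem),
                "replicate": row["replicate"],
                "a_outer_px2": res.a_outer_px2,
                "a_inner_px2": res.a_inner_px2,
                "f_measure": res.f_measure_px2,
                "f_measure_mm2": res.f_measure_calibrated,
            }
        )
    n = len(manifest.table)
    if len(failures) > max_failure_fraction * n:
        raise RunError(
            f"{len(failures)}/{n} images failed measurement "
            f"(> {max_failure_fraction:.0%} tolerated)"
        )
    for f in failures:
        warnings.warn(f"skipped {f['image_path']}: {f['error']}", stacklevel=2)
    return pd.DataFrame(records), failures


def run_assay(
    manifest: ExperimentManifest,
    *,
    alpha: float = 0.05,
    outlier_threshold: float = 3.5,
    nd_epsilon: float | None = None,
    pixel_size_um: float | None = None,
) -> ReportBundle:
    """Measure, filter, test and summarize a whole assay.

    ``nd_epsilon`` defaults to 0.5% of the median A_inner across measured
    colonies, so rasterization crumbs never count as filamentation.
    """
    per_colony, failures = measure_manifest(manifest, pixel_size_um=pixel_size_um)
    if per_colony.empty:
        raise RunError("no image could be measured")
    if nd_epsilon is None:
        nd_epsilon = 0.005 * float(per_colony["a_inner_px2"].median())
    model = FilamentationComparison(
        per_colony[["strain", "dose_uM", "colony_id", "f_measure"]],
        alpha=alpha,
        outlier_threshold=outlier_threshold,
        nd_epsilon=nd_epsilon,
    )
    results = model.fit()
    log = {
        "n_images": len(manifest.table),
        "n_measured": len(per_colony),
        "n_failed": len(failures),
        "alpha": alpha,
        "outlier_threshold": outlier_threshold,
        "nd_epsilon": nd_epsilon,
        "config_hash": _config_hash(manifest.config),
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in vars(manifest.config).items()
        },
        "rng_seed": manifest.rng_seed,
    }
    return ReportBundle(
        per_colony=per_colony, results=results, failures=failures, log=log
    )


def reproduce_printed_tables(
    summaries: pd.DataFrame,
    pairs: pd.DataFrame | Sequence[tuple[str, float, float]],
) -> pd.DataFrame:
    """Recompute relative changes of published group means for chosen pairs.

    ``summaries`` needs columns (strain, dose_uM, mean); ``pairs`` rows name
    (strain, dose_a, dose_b).  A pair whose means are unavailable — or whose
    baseline mean is not positive — yields the gap marker instead of a
    number, mirroring how unreported cells are printed.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(pairs, columns=["strain", "dose_a", "dose_b"])
    means = {
        (r["strain"], float(r["dose_uM"])): float(r["mean"])
        for _, r in summaries.iterrows()
    }
    rows = []
    for _, pr in pairs.iterrows():
        key_a = (pr["strain"], float(pr["dose_a"]))
        key_b = (pr["strain"], float(pr["dose_b"]))
        if key_a not in means or key_b not in means or means[key_a] <= 0:
            value: object = GAP_MARKER
        else:
            value = relative_change(means[key_a], means[key_b])
        rows.append(
            {
                "strain": pr["strain"],
                "dose_a": float(pr["dose_a"]),
                "dose_b": float(pr["dose_b"]),
                "percent_change": value,
            }
        )
    return pd.DataFrame(rows, columns=["strain", "dose_a", "dose_b", "percent_change"])


# --------------------------------------------------------------------------
# fully synthetic assays (render + measure in memory)
# --------------------------------------------------------------------------


def simulate_assay_table(
    dose_specs: Mapping[float, SyntheticColonySpec],
    n_per_group: int,
    rng_seed: int,
    strain: str = "SYN",
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Render and measure ``n_per_group`` colonies per dose; return the table.

    ``dose_specs`` maps each dose to the colony geometry its colonies are
    drawn with; each colony gets a fresh filament-angle/noise seed derived
    from ``rng_seed``.  The preprocessing config defaults to the synthetic
    frame size with an opening radius suited to the filament widths used.
    """
    first = next(iter(dose_specs.values()))
    if config is None:
        config = PreprocessConfig(
            target_resolution=(first.image_width_px, first.image_height_px),
            opening_radius_px=12,
        )
    rng = np.random.default_rng(rng_seed)
    records = []
    for dose, spec in sorted(dose_specs.items()):
        for i in range(n_per_group):
            seed = int(rng.integers(0, 2**31 - 1))
            colony_spec = SyntheticColonySpec(
                **{**vars(spec), "rng_seed": seed}
            )
            image, truth = generate_colony_image(colony_spec)
            res = measure_image(image, config, keep_qc=False)
            records.append(
                {
                    "strain": strain,
                    "dose_uM": float(dose),
                    "colony_id": f"{strain}-{dose:g}-{i:03d}",
                    "f_measure": res.f_measure_px2,
                    "truth_filament_px2": truth.filament_area_px2,
                    "truth_core_px2": truth.core_area_px2,
                    "a_inner_px2": res.a_inner_px2,
                }
            )
    return pd.DataFrame(records)
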