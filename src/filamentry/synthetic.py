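"""Synthetic whole-colony images and f-measure cohorts with known ground truth.

Two generators live here:

* :func:`generate_colony_image` paints a brightfield-like colony — a dense
  circular central mass with straight radial filamentous protrusions — and
  returns the exact pixel-counted areas of the core and of the protrusions.
  This gives the imaging pipeline a benchmark whose answer is known.

* :func:`generate_cohort` draws per-colony f-measure samples for a grid of
  strains × 2-phenylethanol doses from moment-matched lognormal
  distributions, optionally spiked with multiplicative outliers.  This gives
  the statistical chain cohorts with the positive, right-skewed, unequal-
  variance structure the analysis assumes.

Both generators are pure functions of their spec (including ``rng_seed``):
the same spec always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .imaging import ColonyImage

__all__ = [
    "SyntheticColonySpec",
    "GroundTruth",
    "SyntheticCohortSpec",
    "generate_colony_image",
    "generate_cohort",
    "write_image_dataset",
]


@dataclass(frozen=True)
class SyntheticColonySpec:
    """Parametric description of one fake colony image.

    The colony is a filled disk of radius ``core_radius_px`` centred in the
    frame, with ``n_filaments`` straight radial capsules (rectangles with
    rounded tips) of the given length and width attached to the core
    boundary at angles drawn uniformly on [0, 2π).  Filaments may overlap;
    ground truth is computed on the union so no area is double-counted.
    """

    image_width_px: int = 640
    image_height_px: int = 480
    core_radius_px: float = 90.0
    n_filaments: int = 12
    filament_length_px: float = 100.0
    filament_width_px: float = 10.0
    background_level: float = 210.0
    foreground_level: float = 60.0
    noise_sd: float = 8.0
    polarity: str = "dark-colony-on-light"
    angle_placement: str = "uniform"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.core_radius_px <= 0:
            raise ConfigurationError("core_radius_px must be positive")
        if self.n_filaments < 0:
            raise ConfigurationError("n_filaments must be non-negative")
        if self.filament_length_px <= 0 or self.filament_width_px <= 0:
            raise ConfigurationError("filament geometry must be positive")
        if self.n_filaments > 0 and self.filament_width_px >= self.core_radius_px:
            raise ConfigurationError(
                "filament_width_px must be smaller than core_radius_px"
            )
        for level in (self.background_level, self.foreground_level):
            if not 0 <= level <= 255:
                raise ConfigurationError("intensity levels must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.polarity not in ("dark-colony-on-light", "light-colony-on-dark"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if self.angle_placement not in ("uniform", "spaced"):
            raise ConfigurationError(
                f"unknown angle_placement {self.angle_placement!r}"
            )
        # the colony (core + filament + rounded tip) must fit inside the frame
        reach = self.core_radius_px + (
            self.filament_length_px + self.filament_width_px / 2.0
            if self.n_filaments > 0
            else 0.0
        )
        half_extent = min(self.image_width_px, self.image_height_px) / 2.0
        if reach >= half_extent - 1:
            raise ConfigurationError(
                f"colony reach {reach:.1f}px does not fit in a "
                f"{self.image_width_px}x{self.image_height_px} frame"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Exact pixel-counted areas of the noiseless painted mask."""

    core_area_px2: int
    filament_area_px2: int

    @property
    def total_area_px2(self) -> int:
        return self.core_area_px2 + self.filament_area_px2


def _capsule_mask(
    shape: tuple[int, int],
    p0: np.ndarray,
    p1: np.ndarray,
    width: float,
) -> np.ndarray:
    """Boolean mask of a capsule (segment p0→p1 dilated by width/2)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = p1 - p0
    seg_len2 = float(d @ d)
    vx = xx - p0[0]
    vy = yy - p0[1]
    t = np.clip((vx * d[0] + vy * d[1]) / seg_len2, 0.0, 1.0)
    dx = vx - t * d[0]
    dy = vy - t * d[1]
    return dx * dx + dy * dy <= (width / 2.0) ** 2


def paint_colony_mask(spec: SyntheticColonySpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (full colony mask, core disk mask) as boolean arrays.

    Filament angles are the only random ingredient and are drawn from
    ``default_rng(spec.rng_seed)``.
    """
    h, w = spec.image_height_px, spec.image_width_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    core = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.core_radius_px**2

    mask = core.copy()
    rng = np.random.default_rng(spec.rng_seed)
    if spec.angle_placement == "spaced" and spec.n_filaments > 0:
        # random rotation + jittered equal spacing: protrusions stay
        # mutually resolvable instead of merging into an annulus
        step = 2.0 * np.pi / spec.n_filaments
        angles = rng.uniform(0.0, 2.0 * np.pi) + step * (
            np.arange(spec.n_filaments) + rng.uniform(-0.15, 0.15, spec.n_filaments)
        )
    else:
        angles = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_filaments)
    centre = np.array([cx, cy])
    for theta in angles:
        u = np.array([np.cos(theta), np.sin(theta)])
        # anchor slightly inside the core so the capsule is always attached
        p0 = centre + (spec.core_radius_px - 1.0) * u
        p1 = centre + (spec.core_radius_px + spec.filament_length_px) * u
        mask |= _capsule_mask((h, w), p0, p1, spec.filament_width_px)
    return mask, core


def generate_colony_image(
    spec: SyntheticColonySpec,
) -> tuple[ColonyImage, GroundTruth]:
    """Render a colony image and its exact ground-truth areas.

    The noiseless painted mask defines the truth: ``core_area_px2`` is the
    pixel count of the central disk and ``filament_area_px2`` the count of
    painted pixels outside it.  Additive Gaussian noise (``noise_sd``) is
    applied after painting and clipped to [0, 255]; it never changes the
    ground truth.
    """
    mask, core = paint_colony_mask(spec)
    truth = GroundTruth(
        core_area_px2=int(core.sum()),
        filament_area_px2=int((mask & ~core).sum()),
    )

    if spec.polarity == "dark-colony-on-light":
        fg, bg = spec.foreground_level, spec.background_level
    else:
        fg, bg = spec.background_level, spec.foreground_level
    img = np.where(mask, fg, bg).astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed + 1)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return (
        ColonyImage(pixels=img, source_id=f"synthetic-seed{spec.rng_seed}"),
        truth,
    )


# --------------------------------------------------------------------------
# f-measure cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Per-group f-measure sampling plan for a strain × dose grid.

    ``targets`` maps ``(strain, dose_uM)`` to a ``(mean, sd)`` pair; groups
    not listed fall back to ``default_target``.  Samples are drawn from a
    lognormal whose parameters are moment-matched to the target mean/SD,
    which gives the strictly positive, right-skewed draws with SD of the
    same order as the mean seen in real per-colony f-measures.  With
    probability ``outlier_rate`` a draw is multiplied by
    ``outlier_multiplier``.
    """

    strains: Sequence[str] = ("S1",)
    doses_uM: Sequence[float] = (0.0, 100.0, 200.0)
    n_per_group: int = 30
    targets: Mapping[tuple[str, float], tuple[float, float]] = field(
        default_factory=dict
    )
    default_target: tuple[float, float] = (0.5, 0.25)
    family: str = "lognormal"
    outlier_rate: float = 0.0
    outlier_multiplier: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ConfigurationError("n_per_group must be at least 3")
        if self.family != "lognormal":
            raise ConfigurationError(f"unsupported family {self.family!r}")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigurationError("outlier_rate must be a probability")
        if self.outlier_multiplier <= 0:
            raise ConfigurationError("outlier_multiplier must be positive")
        for mean, sd in [self.default_target, *self.targets.values()]:
            if mean <= 0 or sd <= 0:
                raise ConfigurationError("target means and SDs must be positive")

    def target_for(self, strain: str, dose: float) -> tuple[float, float]:
        return self.targets.get((strain, float(dose)), self.default_target)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the requested mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a long-format f-measure table (strain, dose_uM, colony_id, f_measure)."""
    rng = np.random.default_rng(spec.rng_seed)
    records = []
    for strain in spec.strains:
        for dose in spec.doses_uM:
            mean, sd = spec.target_for(strain, dose)
            mu, sigma = _lognormal_params(mean, sd)
            draws = rng.lognormal(mu, sigma, size=spec.n_per_group)
            if spec.outlier_rate > 0:
                hit = rng.random(spec.n_per_group) < spec.outlier_rate
                draws = np.where(hit, draws * spec.outlier_multiplier, draws)
            for i, f in enumerate(draws):
                records.append(
                    {
                        "strain": strain,
                        "dose_uM": float(dose),
                        "colony_id": f"{strain}-{dose:g}-{i:03d}",
                        "f_measure": float(f),
                    }
                )
    return pd.DataFrame.from_records(records)


def write_image_dataset(
    specs: Mapping[str, SyntheticColonySpec],
    out_dir,
    manifest_rows: Mapping[str, Mapping[str, object]] | None = None,
    image_format: str = "png",
) -> pd.DataFrame:
    """Render a set of colony images to ``out_dir`` with manifest + truth CSVs.

    ``specs`` maps an image stem to its colony spec; ``manifest_rows``
    optionally supplies strain/dose/replicate annotations per stem.  Returns
    the manifest DataFrame (also written as ``manifest.csv`` next to a
    ``ground_truth.csv``).
    """
    import imageio.v3 as iio
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, truths = [], []
    for stem, spec in specs.items():
        image, truth = generate_colony_image(spec)
        path = out_dir / f"{stem}.{image_format}"
        iio.imwrite(path, image.pixels)
        row = {"image_path": str(path)}
        if manifest_rows and stem in manifest_rows:
            row.update(manifest_rows[stem])
        manifest.append(row)
        truths.append(
            {
                "image_path": str(path),
                "core_area_px2": truth.core_area_px2,
                "filament_area_px2": truth.filament_area_px2,
            }
        )
    manifest_df = pd.DataFrame(manifest)
    manifest_df.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truths).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest_df
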