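"""Synthetic slice images, amide-I spectra and assay tables.

The generators emulate the statistical structure of a refrigerated
storage study of dry-cured meat slices (lamb, beef, buffalo) sampled on
days 1, 4, 8, 11, 14 and 16 with eight slices per type and day:

* **Images** — the slice colour is synthesised in CIELAB and converted
  to 8-bit sRGB.  Redness (a*) and yellowness (b*) fade linearly with
  storage day; texture is the sum of a thresholded low-pass marbling
  field (fat streaks, correlation length ``marbling_scale``) and a
  high-frequency speckle whose amplitude grows with day
  (``fragmentation_rate``), so co-occurrence contrast rises and
  homogeneity falls as storage progresses.
* **Spectra** — amide-I absorbance traces built as five-Gaussian
  mixtures whose component areas follow prescribed secondary-structure
  percentages, on a descending wavenumber grid at the instrument
  resolution (4 cm^-1), plus an optional linear baseline and noise.
* **Assays** — replicate physicochemical / microbiological measurements
  per storage day around published day means (or a linear drift).

Every generator is bitwise deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import lab2rgb

from .imaging import SliceImage

__all__ = [
    "StorageProfile",
    "SpectrumProfile",
    "AssayProfile",
    "AnalyteSpec",
    "STRUCTURE_NAMES",
    "DEFAULT_AMIDE_CENTERS",
    "SECONDARY_STRUCTURE_PRESETS",
    "ASSAY_PRESETS",
    "generate_slice_image",
    "generate_image_dataset",
    "generate_amide_spectrum",
    "generate_assay_series",
    "drift_feature_table",
    "default_assay_profile",
]

#: secondary-structure classes in canonical order
STRUCTURE_NAMES = (
    "beta_parallel_sheet",
    "random_coil",
    "alpha_helix",
    "beta_turn",
    "beta_antiparallel_sheet",
)

#: default amide-I band centres (cm^-1): midpoints of the assignment windows
DEFAULT_AMIDE_CENTERS = (1625.0, 1645.0, 1656.0, 1670.0, 1690.0)

#: published secondary-structure percentages by (meat type, storage day)
SECONDARY_STRUCTURE_PRESETS: dict[tuple[str, int], tuple[float, ...]] = {
    ("lamb", 1): (9.42, 18.64, 10.16, 38.70, 23.08),
    ("lamb", 16): (6.82, 13.96, 7.05, 39.55, 32.62),
    ("beef", 1): (7.38, 17.68, 5.97, 31.91, 37.07),
    ("beef", 16): (7.03, 16.82, 8.40, 37.89, 29.85),
    ("buffalo", 1): (7.06, 14.58, 6.57, 29.48, 42.30),
    ("buffalo", 16): (6.39, 15.59, 11.25, 33.50, 33.26),
}


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StorageProfile:
    """Design of one simulated storage experiment.

    ``fade_rates`` are the per-day decrements of (a*, b*); negative values
    make the slice less red / less yellow over time.  ``fragmentation_rate``
    is the per-day growth of the speckle amplitude in L* units, so texture
    fragments as storage progresses.  ``marbling_amplitude`` (L* units)
    scales the thresholded low-pass marbling field whose correlation
    length is ``marbling_scale`` pixels.  At most ``max_clip_fraction`` of
    the pixels may clip at the sRGB gamut boundary before generation is
    rejected.
    """

    meat_type: str = "lamb"
    days: tuple[int, ...] = (1, 4, 8, 11, 14, 16)
    base_lab: tuple[float, float, float] = (42.0, 25.0, 9.3)
    fade_rates: tuple[float, float] = (-0.5, -0.35)
    marbling_scale: float = 24.0
    marbling_amplitude: float = 5.0
    fragmentation_rate: float = 0.4
    noise_sd: float = 0.8
    slices_per_day: int = 8
    image_size: tuple[int, int] = (512, 512)  # (width, height)
    max_clip_fraction: float = 0.01

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        object.__setattr__(self, "days", days)
        if any(b <= a for a, b in zip(days, days[1:])) or not days:
            raise ValueError("days must be non-empty and strictly increasing")
        if self.slices_per_day < 1:
            raise ValueError("slices_per_day must be >= 1")
        for name in ("fade_rates", "marbling_scale", "marbling_amplitude",
                     "fragmentation_rate", "noise_sd"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if self.marbling_scale <= 0:
            raise ValueError("marbling_scale must be > 0")
        if self.noise_sd < 0 or self.marbling_amplitude < 0:
            raise ValueError("noise_sd and marbling_amplitude must be >= 0")
        w, h = self.image_size
        if w < 8 or h < 8:
            raise ValueError("image_size too small")
        # the faded mean colour must stay inside the sRGB gamut on every day
        for day in days:
            lab = np.array(self.mean_lab(day), dtype=np.float64)
            rgb = lab2rgb(lab[None, None, :])[0, 0]
            if np.any(rgb <= 1e-9) or np.any(rgb >= 1 - 1e-9):
                raise ValueError(
                    f"mean colour on day {day} falls outside the sRGB gamut; "
                    "reduce the fade applied over the storage period"
                )

    def mean_lab(self, day: int) -> tuple[float, float, float]:
        """Closed-form expected (L*, a*, b*) on a storage day."""
        L0, a0, b0 = self.base_lab
        return (
            L0,
            a0 + self.fade_rates[0] * (day - 1),
            b0 + self.fade_rates[1] * (day - 1),
        )


@dataclass(frozen=True)
class SpectrumProfile:
    """Forward model of an amide-I absorbance spectrum.

    ``structure_proportions`` (percent, summing to 100) set the component
    area fractions of ``total_area`` (absorbance·cm^-1); the wavenumber
    grid runs from ``grid_max`` down to ``grid_min`` at ``grid_step``.
    """

    structure_proportions: tuple[float, ...] = SECONDARY_STRUCTURE_PRESETS[("lamb", 1)]
    centers: tuple[float, ...] = DEFAULT_AMIDE_CENTERS
    sigmas: tuple[float, ...] = (6.0, 6.0, 6.0, 6.0, 6.0)
    total_area: float = 12.0
    baseline: tuple[float, float] = (0.0, 0.0)  # (slope, intercept) vs wavenumber
    noise_sd: float = 0.0
    grid_min: float = 500.0
    grid_max: float = 4000.0
    grid_step: float = 4.0

    def __post_init__(self) -> None:
        p = np.asarray(self.structure_proportions, dtype=np.float64)
        if len(p) != len(self.centers) or len(p) != len(self.sigmas):
            raise ValueError("proportions, centers and sigmas must have equal length")
        # published tables carry two-decimal rounding, so a row may sum to
        # 100 +/- 0.01; such rows are renormalised exactly, anything worse
        # is rejected
        if np.any(p < 0) or abs(p.sum() - 100.0) > 0.05:
            raise ValueError("structure proportions must be >= 0 and sum to 100")
        object.__setattr__(self, "structure_proportions", tuple(p * (100.0 / p.sum())))
        if any(not (1600.0 < c < 1700.0) for c in self.centers):
            raise ValueError("band centres must lie strictly inside 1600-1700 cm^-1")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be > 0")
        if self.grid_step <= 0 or self.grid_min >= self.grid_max:
            raise ValueError("invalid wavenumber grid")
        if self.noise_sd < 0 or self.total_area <= 0:
            raise ValueError("noise_sd must be >= 0 and total_area > 0")

    @property
    def wavenumbers(self) -> np.ndarray:
        """Descending grid, instrument convention."""
        n = int(math.floor((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_max - self.grid_step * np.arange(n)

    @property
    def component_areas(self) -> np.ndarray:
        return self.total_area * np.asarray(self.structure_proportions) / 100.0


@dataclass(frozen=True)
class AnalyteSpec:
    """Generator parameters for one measured analyte.

    Either a linear drift (``day1_mean`` + ``drift``·(day−1)) or explicit
    per-day means (``day_means``, aligned with the profile's days, which
    override the drift).  ``noise_sd`` may be a scalar or per-day sequence.
    """

    day1_mean: float
    drift: float = 0.0
    noise_sd: float | tuple[float, ...] = 0.0
    day_means: tuple[float, ...] | None = None
    lo: float | None = None
    hi: float | None = None

    def mean_on(self, days: Sequence[int]) -> np.ndarray:
        if self.day_means is not None:
            if len(self.day_means) != len(days):
                raise ValueError("day_means must align with profile days")
            return np.asarray(self.day_means, dtype=np.float64)
        d = np.asarray(days, dtype=np.float64)
        return self.day1_mean + self.drift * (d - 1.0)

    def sd_on(self, days: Sequence[int]) -> np.ndarray:
        sd = np.asarray(self.noise_sd, dtype=np.float64)
        if sd.ndim == 0:
            sd = np.full(len(days), float(sd))
        if len(sd) != len(days) or np.any(sd < 0):
            raise ValueError("noise_sd must be a non-negative scalar or per-day sequence")
        return sd


@dataclass(frozen=True)
class AssayProfile:
    """Replicate physicochemical/microbiological series over storage days."""

    analytes: Mapping[str, AnalyteSpec]
    days: tuple[int, ...] = (1, 4, 8, 11, 14, 16)
    replicates: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))
        object.__setattr__(self, "analytes", dict(self.analytes))
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per day")
        if not self.analytes:
            raise ValueError("no analytes specified")
        for name, spec in self.analytes.items():
            means = spec.mean_on(self.days)
            if spec.lo is not None and np.any(means < spec.lo):
                raise ValueError(f"{name}: mean below lower bound {spec.lo}")
            if spec.hi is not None and np.any(means > spec.hi):
                raise ValueError(f"{name}: mean above upper bound {spec.hi}")


#: published day-mean series (storage days 1, 4, 8, 11, 14, 16) per meat type
ASSAY_PRESETS: dict[str, dict[str, AnalyteSpec]] = {
    "lamb": {
        "moisture_pct": AnalyteSpec(45.66, day_means=(45.66, 45.08, 45.54, 37.07, 35.15, 34.93),
                                    noise_sd=(2.86, 3.35, 2.47, 2.58, 3.80, 2.51), lo=0, hi=100),
        "water_activity": AnalyteSpec(0.90, noise_sd=0.01, lo=0, hi=1),
        "hue_angle_deg": AnalyteSpec(20.45, day_means=(20.45, 20.66, 20.29, 17.33, 15.84, 14.80),
                                     noise_sd=(1.36, 0.65, 1.52, 2.18, 1.52, 2.02)),
        "firmness_N": AnalyteSpec(5.07, day_means=(5.07, 5.42, 8.56, 9.25, 11.07, 11.62),
                                  noise_sd=(0.62, 0.51, 0.25, 1.21, 2.35, 1.31), lo=0),
        "tbars_mg_mda_kg": AnalyteSpec(5.10, day_means=(5.10, 5.33, 4.90, 5.31, 5.00, 6.68),
                                       noise_sd=(0.08, 0.22, 0.17, 0.22, 0.15, 0.16), lo=0),
        "apc_log_cfu_g": AnalyteSpec(4.0, drift=-0.03, noise_sd=0.15, lo=0),
        "lab_log_cfu_g": AnalyteSpec(4.0, drift=-0.03, noise_sd=0.15, lo=0),
        "yeast_log_cfu_g": AnalyteSpec(3.0, drift=0.0, noise_sd=0.15, lo=0),
    },
    "beef": {
        "moisture_pct": AnalyteSpec(51.62, day_means=(51.62, 50.77, 42.18, 42.15, 41.52, 40.37),
                                    noise_sd=(2.61, 3.80, 0.75, 2.80, 2.87, 1.75), lo=0, hi=100),
        "water_activity": AnalyteSpec(0.87, noise_sd=0.01, lo=0, hi=1),
        "hue_angle_deg": AnalyteSpec(26.42, day_means=(26.42, 27.57, 27.90, 25.83, 25.35, 24.59),
                                     noise_sd=(1.15, 1.56, 1.25, 2.83, 1.79, 1.55)),
        "firmness_N": AnalyteSpec(3.70, day_means=(3.70, 4.12, 5.06, 4.95, 5.19, 5.24),
                                  noise_sd=(0.32, 0.36, 0.61, 0.47, 0.78, 0.59), lo=0),
        "tbars_mg_mda_kg": AnalyteSpec(0.57, day_means=(0.57, 0.66, 0.84, 0.84, 0.86, 0.94),
                                       noise_sd=(0.03, 0.04, 0.04, 0.03, 0.02, 0.03), lo=0),
        "apc_log_cfu_g": AnalyteSpec(4.0, drift=-0.03, noise_sd=0.15, lo=0),
        "lab_log_cfu_g": AnalyteSpec(4.0, drift=-0.03, noise_sd=0.15, lo=0),
        "yeast_log_cfu_g": AnalyteSpec(3.0, drift=0.0, noise_sd=0.15, lo=0),
    },
    "buffalo": {
        "moisture_pct": AnalyteSpec(44.23, day_means=(44.23, 39.50, 37.64, 34.55, 34.18, 35.11),
                                    noise_sd=(3.75, 2.53, 2.44, 2.62, 1.92, 1.93), lo=0, hi=100),
        "water_activity": AnalyteSpec(0.84, noise_sd=0.01, lo=0, hi=1),
        "hue_angle_deg": AnalyteSpec(23.12, day_means=(23.12, 22.05, 23.99, 22.90, 25.82, 25.16),
                                     noise_sd=(0.99, 2.52, 2.05, 2.14, 3.75, 1.30)),
        "firmness_N": AnalyteSpec(4.48, day_means=(4.48, 5.46, 5.75, 8.87, 9.15, 9.08),
                                  noise_sd=(0.19, 0.24, 0.50, 1.04, 1.80, 1.08), lo=0),
        "tbars_mg_mda_kg": AnalyteSpec(0.97, day_means=(0.97, 1.23, 1.29, 1.47, 1.62, 1.65),
                                       noise_sd=(0.04, 0.05, 0.06, 0.04, 0.05, 0.06), lo=0),
        "apc_log_cfu_g": AnalyteSpec(4.0, drift=-0.03, noise_sd=0.15, lo=0),
        "lab_log_cfu_g": AnalyteSpec(4.0, drift=-0.03, noise_sd=0.15, lo=0),
        "yeast_log_cfu_g": AnalyteSpec(3.0, drift=0.0, noise_sd=0.15, lo=0),
    },
}


def default_assay_profile(meat_type: str = "lamb", replicates: int = 8) -> AssayProfile:
    """Assay profile parameterised from the published storage series."""
    if meat_type not in ASSAY_PRESETS:
        raise ValueError(f"no assay preset for {meat_type!r}; choose from {sorted(ASSAY_PRESETS)}")
    return AssayProfile(analytes=ASSAY_PRESETS[meat_type], replicates=replicates)


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------


def _image_rng(seed: int, day: int, slice_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(day), int(slice_index)]))


def generate_slice_image(
    profile: StorageProfile, day: int, slice_index: int, seed: int
) -> SliceImage:
    """One synthetic slice photograph for a given storage day.

    The Lab pixel field is the day's faded mean colour plus a thresholded
    low-pass marbling field and day-growing speckle on L*, plus white
    noise on all three channels, converted to 8-bit sRGB.  Deterministic
    for fixed (profile, day, slice_index, seed).
    """
    if day not in profile.days:
        raise ValueError(f"day {day} not in profile days {profile.days}")
    rng = _image_rng(seed, day, slice_index)
    w, h = profile.image_size
    L0, a0, b0 = profile.mean_lab(day)

    # marbling: thresholded low-pass filtered white noise, zero mean
    g = gaussian_filter(rng.standard_normal((h, w)), sigma=profile.marbling_scale / 2.0)
    marbling = profile.marbling_amplitude * (np.where(g > 0, 0.5, -0.5))

    speckle_amp = profile.fragmentation_rate * (day - 1)
    speckle = speckle_amp * rng.standard_normal((h, w))
    noise = profile.noise_sd * rng.standard_normal((h, w, 3))

    lab = np.empty((h, w, 3), dtype=np.float64)
    lab[..., 0] = L0 + marbling + speckle + noise[..., 0]
    lab[..., 1] = a0 + noise[..., 1]
    lab[..., 2] = b0 + noise[..., 2]

    rgb = lab2rgb(lab)
    clipped = np.any((rgb <= 0.0) | (rgb >= 1.0), axis=-1)
    frac = float(clipped.mean())
    if frac > profile.max_clip_fraction:
        raise ValueError(
            f"{frac:.1%} of pixels clip at the sRGB gamut (limit "
            f"{profile.max_clip_fraction:.1%}); adjust the profile"
        )
    pixels = np.rint(rgb * 255.0).astype(np.uint8)
    return SliceImage(pixels=pixels, meat_type=profile.meat_type, day=day, slice_id=slice_index)


def generate_image_dataset(profile: StorageProfile, seed: int) -> list[SliceImage]:
    """One labelled image per (day, slice): |days| x slices_per_day images."""
    return [
        generate_slice_image(profile, day, s, seed)
        for day in profile.days
        for s in range(profile.slices_per_day)
    ]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def generate_amide_spectrum(profile: SpectrumProfile, seed: int = 0):
    """Forward-model absorbance trace on the descending wavenumber grid.

    absorbance(nu) = slope·nu + intercept + Σ_k A_k exp(−(nu−c_k)²/2σ_k²)
    with component amplitudes A_k = area_k / (σ_k √(2π)), plus Gaussian
    noise of SD ``noise_sd``.
    """
    from .ftir import Spectrum  # deferred to avoid a cycle at import time

    rng = np.random.default_rng(seed)
    nu = profile.wavenumbers
    slope, intercept = profile.baseline
    absorbance = slope * nu + intercept
    for area, c, s in zip(profile.component_areas, profile.centers, profile.sigmas):
        absorbance = absorbance + area / (s * math.sqrt(2 * math.pi)) * np.exp(
            -((nu - c) ** 2) / (2 * s**2)
        )
    if profile.noise_sd > 0:
        absorbance = absorbance + profile.noise_sd * rng.standard_normal(nu.shape)
    return Spectrum(wavenumbers=nu, absorbance=absorbance, metadata={"seed": seed})


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------


def generate_assay_series(profile: AssayProfile, seed: int) -> pd.DataFrame:
    """Tidy replicate table (day, replicate, analyte, value), seeded."""
    rng = np.random.default_rng(seed)
    rows = []
    for name in profile.analytes:  # insertion order: deterministic
        spec = profile.analytes[name]
        means = spec.mean_on(profile.days)
        sds = spec.sd_on(profile.days)
        for day, m, sd in zip(profile.days, means, sds):
            values = m + sd * rng.standard_normal(profile.replicates)
            if spec.lo is not None:
                values = np.maximum(values, spec.lo)
            if spec.hi is not None:
                values = np.minimum(values, spec.hi)
            for r, v in enumerate(values):
                rows.append({"day": day, "replicate": r, "analyte": name, "value": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature-drift series (regression benchmarks)
# ---------------------------------------------------------------------------


def drift_feature_table(
    days: Sequence[int] = (1, 4, 8, 11, 14, 16),
    n_per_day: int = 64,
    feature_ranges: Mapping[str, tuple[float, float]] = {
        "mean_intensity": (120.0, 90.0),
        "run_percentage": (0.45, 0.75),
        "contrast": (2.0, 9.0),
    },
    noise_frac: float = 0.001,
    seed: int = 42,
) -> pd.DataFrame:
    """Feature table whose columns drift linearly from day min to day max.

    Each feature moves linearly between its (first-day, last-day) values
    with additive Gaussian noise of SD ``noise_frac`` times its total
    drift range — a near-noiseless monotone benchmark for storage-day
    regression.  Returns a DataFrame with a ``day`` column plus features.
    """
    rng = np.random.default_rng(seed)
    days = list(days)
    d0, d1 = days[0], days[-1]
    rows = {"day": np.repeat(days, n_per_day).astype(float)}
    t = (rows["day"] - d0) / (d1 - d0)
    for name, (start, stop) in feature_ranges.items():
        span = abs(stop - start)
        vals = start + (stop - start) * t + noise_frac * span * rng.standard_normal(t.shape)
        rows[name] = vals
    return pd.DataFrame(rows)
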