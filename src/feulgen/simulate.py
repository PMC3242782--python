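"""Seeded synthetic nuclei for Feulgen densitometry and TUNEL scoring.

No microscope data ships with this package; every downstream stage is
exercised on synthetic nuclei with known ground truth instead.  A nucleus is
an elliptical mask whose in-mask pixels are partitioned into two chromatin
compartments — spatially coherent condensed foci and a diffuse background —
by thresholding a smoothed Gaussian random field at the quantile that yields
the requested condensed-area fraction.  That construction gives blob-like
foci with exact-by-construction area control: the realized fraction differs
from the request only by pixel-count granularity.

Mean optical densities default to 0.05 (diffuse) and 0.30 (condensed),
straddling the 0.100 condensed-chromatin cutoff; Gaussian pixel noise is
added and the result clipped at 0 (absorbance is non-negative).  When a
target integrated optical density is requested, in-mask ODs are rescaled so
their sum matches it, which is how DNA-content (ploidy) classes are
simulated.

TUNEL cells are rendered in color: a methyl-green-toned nucleus whose dark
DAB spots have 8-bit luminance inside the detection gray window, over a
near-white background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .densitometry import NucleusMask
from .image import DEFAULT_PIXEL_PITCH_UM, AbsorbanceImage
from .tunel import DEFAULT_AREA_THRESHOLDS, DEFAULT_GRAY_WINDOW, luminance_8bit, rank_from_relative_area


class DegenerateGeometryError(ValueError):
    """The nuclear geometry is too small to realize the requested layout."""


@dataclass(frozen=True)
class NucleusSimParams:
    """Ground-truth parameters of one synthetic nucleus.

    ``condensed_fraction`` is the target fraction of nuclear area occupied by
    condensed foci; ``focus_scale_px`` the spatial correlation length of the
    foci; ``target_iod`` an optional total integrated OD to rescale to
    (``None`` leaves the IOD unconstrained).  ``axis_ratio_range`` bounds the
    minor/major axis ratio of the elliptical mask, which preserves the area
    of a circle of the given radius.
    """

    nucleus_radius_px: float
    condensed_fraction: float
    od_diffuse: float = 0.05
    od_condensed: float = 0.30
    od_noise_sd: float = 0.01
    focus_scale_px: float = 3.0
    target_iod: float | None = None
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    axis_ratio_range: tuple[float, float] = (0.75, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        if not 0.0 <= self.condensed_fraction <= 1.0:
            raise ValueError("condensed_fraction must be in [0, 1]")
        if not self.od_condensed > self.od_diffuse >= 0.0:
            raise ValueError("need od_condensed > od_diffuse >= 0")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be >= 0")
        if self.focus_scale_px <= 0:
            raise ValueError("focus_scale_px must be positive")
        if self.target_iod is not None and self.target_iod <= 0:
            raise ValueError("target_iod must be positive when set")
        lo, hi = self.axis_ratio_range
        if not 0 < lo <= hi <= 1.0:
            raise ValueError("axis_ratio_range must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class SimTruth:
    """Realized (not merely requested) ground truth of one synthetic nucleus."""

    true_condensed_fraction: float
    true_iod: float
    true_nuclear_area_um2: float
    seed: int
    params: NucleusSimParams


def _elliptical_mask(params: NucleusSimParams, rng: np.random.Generator) -> np.ndarray:
    """Area-preserving ellipse with random axis ratio and orientation."""
    r = params.nucleus_radius_px
    lo, hi = params.axis_ratio_range
    q = rng.uniform(lo, hi)  # minor/major axis ratio
    a, b = r / math.sqrt(q), r * math.sqrt(q)
    theta = rng.uniform(0.0, math.pi)
    size = int(math.ceil(2 * a)) + 8
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - c) * math.cos(theta) + (yy - c) * math.sin(theta)
    v = -(xx - c) * math.sin(theta) + (yy - c) * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _coherent_subset(
    mask: np.ndarray, n_select: int, scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``n_select`` in-mask pixels forming coherent blobs.

    A white-noise field is smoothed to correlation length ``scale_px`` and the
    top ``n_select`` in-mask field values are selected — i.e. the field is
    thresholded at the quantile realizing the requested count exactly.
    """
    field_vals = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=scale_px)
    selected = np.zeros(mask.shape, dtype=bool)
    if n_select <= 0:
        return selected
    in_mask = np.flatnonzero(mask)
    order = np.argsort(field_vals.ravel()[in_mask], kind="stable")[::-1]
    selected.ravel()[in_mask[order[:n_select]]] = True
    return selected


def generate_nucleus(
    params: NucleusSimParams,
) -> tuple[AbsorbanceImage, NucleusMask, SimTruth]:
    """Render one synthetic Feulgen-stained nucleus.

    Returns the absorbance image, the generative nuclear mask, and the
    realized ground truth.  Identical params (including seed) give
    bit-identical images.

    Raises
    ------
    DegenerateGeometryError
        If the mask is too small to carry the requested condensed fraction.
    """
    rng = np.random.default_rng(params.seed)
    mask = _elliptical_mask(params, rng)
    n = int(mask.sum())
    if n < 16:
        raise DegenerateGeometryError(f"nuclear mask of {n} px is too small to populate")
    k = int(round(params.condensed_fraction * n))
    if params.condensed_fraction > 0 and k == 0:
        raise DegenerateGeometryError(
            f"radius {params.nucleus_radius_px} px cannot realize a condensed "
            f"fraction of {params.condensed_fraction}"
        )

    condensed = _coherent_subset(mask, k, params.focus_scale_px, rng)
    od = np.zeros(mask.shape, dtype=float)
    od[mask] = params.od_diffuse
    od[condensed] = params.od_condensed
    if params.od_noise_sd > 0:
        od[mask] += rng.normal(0.0, params.od_noise_sd, size=n)
    np.clip(od, 0.0, None, out=od)

    if params.target_iod is not None:
        total = od[mask].sum()
        if total <= 0:
            raise DegenerateGeometryError("cannot rescale an all-zero nucleus to a target IOD")
        od[mask] *= params.target_iod / total

    img = AbsorbanceImage(od, pixel_pitch_um=params.pixel_pitch_um, source="synthetic")
    truth = SimTruth(
        true_condensed_fraction=k / n,
        true_iod=float(od[mask].sum()),
        true_nuclear_area_um2=n * params.pixel_pitch_um**2,
        seed=params.seed,
        params=params,
    )
    return img, NucleusMask.from_bool_array(mask), truth


# ---------------------------------------------------------------------------
# populations


@dataclass(frozen=True)
class PopulationPreset:
    """Distributional recipe for a nucleus population.

    Per-nucleus condensed fractions are logit-normal — normal with spread
    ``condensed_fraction_logit_sd`` on the log-odds scale, so the *median*
    fraction equals ``condensed_fraction_median`` exactly and values stay in
    (0, 1).  Radii are normal, floored at ``radius_min_px``.
    """

    condensed_fraction_median: float
    condensed_fraction_logit_sd: float = 0.5
    radius_mean_px: float = 36.0
    radius_sd_px: float = 3.0
    radius_min_px: float = 30.0
    od_diffuse: float = 0.05
    od_condensed: float = 0.30
    od_noise_sd: float = 0.01
    focus_scale_px: float = 3.0
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM


#: Default presets: the control median condensed fraction (0.60) and the
#: decondensed one (0.40) mirror the direction and rough magnitude of the
#: median Sc% shift observed when HDAC-inhibited cells are compared with
#: untreated controls.
PRESETS: dict[str, PopulationPreset] = {
    "control": PopulationPreset(condensed_fraction_median=0.60),
    "decondensed": PopulationPreset(condensed_fraction_median=0.40),
}


def generate_population(
    preset: str | PopulationPreset,
    n: int,
    seed: int,
    *,
    overrides: Mapping[str, Any] | None = None,
    target_iods: Sequence[float] | None = None,
) -> list[tuple[AbsorbanceImage, NucleusMask, SimTruth]]:
    """Generate ``n`` seeded nuclei from a named preset (or explicit recipe).

    ``overrides`` replaces preset fields; ``target_iods`` (length ``n``)
    pins each nucleus's integrated OD, e.g. to simulate ploidy classes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(preset, str):
        try:
            recipe = PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}") from None
    else:
        recipe = preset
    if overrides:
        recipe = replace(recipe, **dict(overrides))
    if target_iods is not None and len(target_iods) != n:
        raise ValueError("target_iods must have length n")

    rng = np.random.default_rng(seed)
    mu = math.log(recipe.condensed_fraction_median / (1 - recipe.condensed_fraction_median))
    logits = rng.normal(mu, recipe.condensed_fraction_logit_sd, size=n)
    fractions = 1.0 / (1.0 + np.exp(-logits))
    radii = np.maximum(rng.normal(recipe.radius_mean_px, recipe.radius_sd_px, n), recipe.radius_min_px)
    child_seeds = rng.integers(0, 2**31, size=n)

    out = []
    for i in range(n):
        params = NucleusSimParams(
            nucleus_radius_px=float(radii[i]),
            condensed_fraction=float(fractions[i]),
            od_diffuse=recipe.od_diffuse,
            od_condensed=recipe.od_condensed,
            od_noise_sd=recipe.od_noise_sd,
            focus_scale_px=recipe.focus_scale_px,
            target_iod=None if target_iods is None else float(target_iods[i]),
            pixel_pitch_um=recipe.pixel_pitch_um,
            seed=int(child_seeds[i]),
        )
        out.append(generate_nucleus(params))
    return out


def draw_ploidy_iods(
    n: int,
    anchor_iod: float,
    rng: np.random.Generator,
    *,
    multipliers: Sequence[float] = (1.0, 1.5, 2.0),
    weights: Sequence[float] = (0.70, 0.20, 0.10),
    rel_sd: float = 0.05,
) -> np.ndarray:
    """Draw per-nucleus target IODs as a mixture of DNA-content classes.

    The default mixture puts 70% of nuclei at the 2C anchor, 20% at 1.5×
    (S phase) and 10% at 2× (G2/tetraploid), each with 5% relative spread —
    a cycling population dominated by G1.
    """
    comp = rng.choice(len(multipliers), size=n, p=np.asarray(weights) / np.sum(weights))
    base = anchor_iod * np.asarray(multipliers)[comp]
    return base * np.exp(rng.normal(0.0, rel_sd, size=n))


def truth_table(truths: Sequence[SimTruth], ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabulate ground truth with the standard (id, seed, truth...) layout."""
    if ids is None:
        ids = [f"nucleus_{i:04d}" for i in range(len(truths))]
    return pd.DataFrame(
        {
            "id": list(ids),
            "seed": [t.seed for t in truths],
            "true_condensed_fraction": [t.true_condensed_fraction for t in truths],
            "true_iod": [t.true_iod for t in truths],
            "true_nuclear_area_um2": [t.true_nuclear_area_um2 for t in truths],
        }
    )


# ---------------------------------------------------------------------------
# TUNEL cells

#: RGB tones chosen so spot luminance (82) falls inside the default 60–100
#: detection window and nucleus (180) / background (245) fall outside it.
TUNEL_COLORS = {
    "background": (245, 245, 245),
    "nucleus": (150, 200, 160),  # methyl-green counterstain
    "spot": (120, 70, 40),  # dark DAB product
}


@dataclass(frozen=True)
class TunelSimTruth:
    """Realized ground truth of one synthetic TUNEL cell."""

    relative_area_pct: float
    rank: str
    seed: int


def generate_tunel_cell(
    spot_coverage: float,
    nucleus_radius_px: float = 30.0,
    seed: int = 0,
    *,
    colors: Mapping[str, tuple[int, int, int]] = TUNEL_COLORS,
    gray_window: tuple[int, int] = DEFAULT_GRAY_WINDOW,
    area_thresholds: tuple[float, float] = DEFAULT_AREA_THRESHOLDS,
    focus_scale_px: float = 2.0,
) -> tuple[np.ndarray, float, str]:
    """Render one synthetic TUNEL cell as an 8-bit RGB image.

    Dark spots cover ``spot_coverage`` of the nuclear area (up to pixel
    granularity); their luminance is validated to fall inside the detection
    gray window so a noise-free round trip through spot detection recovers
    the truth exactly.  Returns (image, true relative spot area %, true rank).
    """
    if not 0.0 <= spot_coverage <= 1.0:
        raise ValueError("spot_coverage must be in [0, 1]")
    low, high = gray_window
    spot_lum = int(luminance_8bit(np.array([[colors["spot"]]], dtype=np.uint8))[0, 0])
    if not low <= spot_lum <= high:
        raise ValueError(f"spot color luminance {spot_lum} falls outside window [{low}, {high}]")
    for name in ("nucleus", "background"):
        lum = int(luminance_8bit(np.array([[colors[name]]], dtype=np.uint8))[0, 0])
        if low <= lum <= high:
            raise ValueError(f"{name} color luminance {lum} falls inside the spot window")

    geom = NucleusSimParams(nucleus_radius_px=nucleus_radius_px, condensed_fraction=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    mask = _elliptical_mask(geom, rng)
    n = int(mask.sum())
    if n < 16:
        raise DegenerateGeometryError(f"nuclear mask of {n} px is too small to populate")
    k = int(round(spot_coverage * n))
    spots = _coherent_subset(mask, k, focus_scale_px, rng)

    img = np.empty(mask.shape + (3,), dtype=np.uint8)
    img[...] = colors["background"]
    img[mask] = colors["nucleus"]
    img[spots] = colors["spot"]

    rel = 100.0 * k / n
    return img, rel, rank_from_relative_area(rel, area_thresholds)


def generate_tunel_condition(
    n: int,
    seed: int,
    *,
    positive_prob: float,
    coverage_beta: tuple[float, float],
    nucleus_radius_px: float = 30.0,
) -> Iterator[tuple[np.ndarray, float, str]]:
    """Yield ``n`` TUNEL cells for one experimental condition.

    Each cell is TUNEL-positive with probability ``positive_prob``; positive
    cells draw their spot coverage from a Beta distribution (shape params
    ``coverage_beta``), negative cells have coverage 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    positive = rng.random(n) < positive_prob
    coverages = np.where(positive, rng.beta(*coverage_beta, size=n), 0.0)
    child_seeds = rng.integers(0, 2**31, size=n)
    for cov, s in zip(coverages, child_seeds):
        yield generate_tunel_cell(float(cov), nucleus_radius_px, int(s))


def write_truth_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(Path(path), index=False, float_format="%.10g", lineterminator="\n")
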