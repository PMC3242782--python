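"""Per-nucleus Feulgen densitometry.

Nuclei are segmented from an absorbance image by the background rule (pixels
with OD no higher than the background threshold, default 0.020, are removed;
the remainder is split into 8-connected components), and each nucleus is
reduced to the karyometric parameters

* ``A_T`` — total integrated absorbance (the Feulgen-DNA value / IOD),
* ``A_C`` — integrated absorbance over the condensed-chromatin cutoff
  (default OD 0.100), and ``Ac% = 100·A_C/A_T``,
* ``S_T`` — nuclear area in µm², ``S_C`` — area above the cutoff, and
  ``Sc% = 100·S_C/S_T``,
* ``AAR = (A_C/S_C)/(A_T/S_T)`` — the average absorption ratio, how many
  times the mean absorbance of condensed chromatin exceeds that of the whole
  nucleus.  AAR >= 1 whenever condensed pixels exist (they are the top-OD
  subset); it is undefined (NaN) when no pixel exceeds the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from .image import AbsorbanceImage

#: grid points with OD no higher than this are background and removed
DEFAULT_BACKGROUND_THRESHOLD = 0.020
#: pixels with OD strictly above this count as condensed chromatin
DEFAULT_CONDENSED_CUTOFF = 0.100
#: connected components smaller than this are discarded as debris
DEFAULT_MIN_AREA_PX = 50


@dataclass(frozen=True)
class NucleusMask:
    """Pixel-coordinate set of one segmented nucleus."""

    pixels: np.ndarray  # (N, 2) int array of (row, col) coordinates
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValueError("mask needs a non-empty (N, 2) pixel coordinate array")
        object.__setattr__(self, "pixels", px)

    @property
    def area_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), inclusive."""
        mins = self.pixels.min(axis=0)
        maxs = self.pixels.max(axis=0)
        return (int(mins[0]), int(mins[1]), int(maxs[0]), int(maxs[1]))

    def to_bool_array(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        out[self.pixels[:, 0], self.pixels[:, 1]] = True
        return out

    @classmethod
    def from_bool_array(cls, arr: np.ndarray) -> "NucleusMask":
        rows, cols = np.nonzero(arr)
        return cls(np.column_stack([rows, cols]), arr.shape)  # type: ignore[arg-type]


@dataclass(frozen=True)
class NucleusMeasurement:
    """The karyometric record of one nucleus."""

    a_t: float  # total integrated absorbance (arbitrary units)
    a_c: float  # integrated absorbance over the cutoff
    ac_pct: float  # 100 * A_C / A_T
    s_t_um2: float  # nuclear area, µm²
    s_c_um2: float  # condensed-chromatin area, µm²
    sc_pct: float  # 100 * S_C / S_T
    aar: float  # (A_C/S_C) / (A_T/S_T); NaN when S_C == 0
    cutoff: float
    background_threshold: float
    n_pixels: int
    n_condensed_pixels: int

    @property
    def aar_defined(self) -> bool:
        return not math.isnan(self.aar)


def segment_nuclei(
    img: AbsorbanceImage,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    *,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> list[NucleusMask]:
    """Segment nuclei by the background rule.

    Pixels with OD <= ``background_threshold`` are removed; the remaining
    pixels are grouped into 8-connected components and components below
    ``min_area_px`` are discarded.  Returns an empty list when nothing
    survives.
    """
    foreground = img.values > background_threshold
    labels = skmeasure.label(foreground, connectivity=2)
    masks: list[NucleusMask] = []
    for region in skmeasure.regionprops(labels):
        if region.area < min_area_px:
            continue
        masks.append(NucleusMask(region.coords.copy(), img.shape))
    return masks


def measure_nucleus(
    img: AbsorbanceImage,
    mask: NucleusMask,
    cutoff: float = DEFAULT_CONDENSED_CUTOFF,
    *,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> NucleusMeasurement:
    """Compute the karyometric parameters of one nucleus.

    The condensed set is the in-mask pixels with OD strictly above ``cutoff``.
    All parameters are histogram functionals — they depend only on the
    multiset of in-mask OD values and the pixel pitch, not on pixel positions.
    """
    od = img.values[mask.pixels[:, 0], mask.pixels[:, 1]]
    if od.size == 0:
        raise ValueError("empty nucleus mask")
    pixel_area = img.pixel_area_um2

    # exactly-rounded sums: invariant to pixel order, so shuffling a mask's
    # pixels can never change the integrated absorbances
    a_t = math.fsum(od)
    s_t = od.size * pixel_area
    condensed = od > cutoff
    n_c = int(condensed.sum())
    a_c = math.fsum(od[condensed])
    s_c = n_c * pixel_area

    ac_pct = 100.0 * a_c / a_t if a_t > 0 else 0.0
    sc_pct = 100.0 * s_c / s_t
    aar = (a_c / s_c) / (a_t / s_t) if n_c > 0 else float("nan")
    return NucleusMeasurement(
        a_t=a_t,
        a_c=a_c,
        ac_pct=ac_pct,
        s_t_um2=s_t,
        s_c_um2=s_c,
        sc_pct=sc_pct,
        aar=aar,
        cutoff=cutoff,
        background_threshold=background_threshold,
        n_pixels=int(od.size),
        n_condensed_pixels=n_c,
    )


def measure_image(
    img: AbsorbanceImage,
    *,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    cutoff: float = DEFAULT_CONDENSED_CUTOFF,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> list[NucleusMeasurement]:
    """Segment an image and measure every retained nucleus."""
    masks = segment_nuclei(img, background_threshold, min_area_px=min_area_px)
    return [
        measure_nucleus(img, m, cutoff, background_threshold=background_threshold) for m in masks
    ]


_CSV_COLUMNS = [
    "image_id",
    "nucleus_id",
    "A_T",
    "A_C",
    "Ac_pct",
    "S_T_um2",
    "S_C_um2",
    "Sc_pct",
    "AAR",
    "cutoff",
    "background_threshold",
]


def measurements_to_frame(
    measurements: Sequence[NucleusMeasurement],
    *,
    image_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tabulate measurements with the standard per-nucleus column layout."""
    ids = list(image_ids) if image_ids is not None else [""] * len(measurements)
    if len(ids) != len(measurements):
        raise ValueError("image_ids length must match measurements")
    rows = [
        {
            "image_id": img_id,
            "nucleus_id": i,
            "A_T": m.a_t,
            "A_C": m.a_c,
            "Ac_pct": m.ac_pct,
            "S_T_um2": m.s_t_um2,
            "S_C_um2": m.s_c_um2,
            "Sc_pct": m.sc_pct,
            "AAR": m.aar,
            "cutoff": m.cutoff,
            "background_threshold": m.background_threshold,
        }
        for i, (img_id, m) in enumerate(zip(ids, measurements))
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_measurements_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(Path(path), index=False, float_format="%.10g", lineterminator="\n")
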