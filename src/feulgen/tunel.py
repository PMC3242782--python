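"""TUNEL positivity scoring by relative dark-spot area.

TUNEL-positive nuclei carry dark (DAB) brown spots over a methyl-green
counterstain.  Spots are segmented by a fixed gray window — in-nucleus pixels
whose 8-bit gray value lies in [60, 100] inclusive — and each cell is scored
by the fraction of its nuclear area the spots cover:

* negative — no spot pixels,
* weak     — spots over less than 5% of the nuclear area,
* moderate — 5% up to (but not including) 50%,
* strong   — 50% or more.

Scoring is deliberately area-based, not mean-gray-based: the DAB reaction
product does not follow the Beer-Lambert law, so mean gray value is not a
valid quantitative readout for this assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("negative", "weak", "moderate", "strong")
POSITIVE_RANKS = ("weak", "moderate", "strong")

#: inclusive 8-bit gray window defining "dark" DAB spot pixels
DEFAULT_GRAY_WINDOW = (60, 100)
#: relative-area breakpoints (%) between weak/moderate and moderate/strong
DEFAULT_AREA_THRESHOLDS = (5.0, 50.0)

# ITU-R BT.601 luma weights; DAB spot darkness is a broadband property, so
# plain luminance is used unless a single camera channel is requested.
_LUMA_601 = np.array([0.299, 0.587, 0.114])


def luminance_8bit(img: np.ndarray) -> np.ndarray:
    """8-bit luminance of a gray or RGB(A) uint8 image (BT.601, rounded)."""
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] >= 3:
        y = arr[..., :3].astype(float) @ _LUMA_601
        return np.clip(np.round(y), 0, 255).astype(np.uint8)
    raise ValueError(f"expected 2-D gray or 3-D color image, got shape {arr.shape}")


def detect_spots(
    img: np.ndarray,
    nucleus_mask: np.ndarray,
    low: int = DEFAULT_GRAY_WINDOW[0],
    high: int = DEFAULT_GRAY_WINDOW[1],
    *,
    channel: str | int = "luminance",
) -> np.ndarray:
    """Boolean mask of in-nucleus pixels inside the dark-spot gray window.

    ``channel`` selects what "gray value" means for color input: the default
    ``"luminance"`` (BT.601) or an integer channel index of the color image.
    """
    if not (0 <= low <= high <= 255):
        raise ValueError(f"invalid gray window [{low}, {high}]: need 0 <= low <= high <= 255")
    arr = np.asarray(img)
    if isinstance(channel, int):
        if arr.ndim != 3:
            raise ValueError("channel index requires a color image")
        gray = arr[..., channel]
    else:
        gray = luminance_8bit(arr)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if nucleus_mask.shape != gray.shape:
        raise ValueError("nucleus mask shape must match image shape")
    return nucleus_mask & (gray >= low) & (gray <= high)


def rank_from_relative_area(
    relative_area_pct: float,
    thresholds: tuple[float, float] = DEFAULT_AREA_THRESHOLDS,
) -> str:
    """Classify a relative spot area (%) as negative/weak/moderate/strong."""
    weak_lt, strong_ge = thresholds
    if relative_area_pct < 0 or relative_area_pct > 100:
        raise ValueError("relative area must be in [0, 100]")
    if relative_area_pct == 0:
        return "negative"
    if relative_area_pct < weak_lt:
        return "weak"
    if relative_area_pct < strong_ge:
        return "moderate"
    return "strong"


@dataclass(frozen=True)
class TunelScore:
    """Relative dark-spot area of one cell and its positivity rank."""

    nucleus_area_px: int
    spot_area_px: int
    relative_area_pct: float
    rank: str

    def __post_init__(self) -> None:
        if self.spot_area_px > self.nucleus_area_px:
            raise ValueError("spot area cannot exceed nucleus area")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


def classify_tunel(
    nucleus_mask: np.ndarray,
    spot_mask: np.ndarray,
    thresholds: tuple[float, float] = DEFAULT_AREA_THRESHOLDS,
) -> TunelScore:
    """Score one cell from its nucleus and spot masks."""
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    spot_mask = np.asarray(spot_mask, dtype=bool)
    n_nuc = int(nucleus_mask.sum())
    if n_nuc < 1:
        raise ValueError("empty nucleus mask")
    n_spot = int((spot_mask & nucleus_mask).sum())
    rel = 100.0 * n_spot / n_nuc
    return TunelScore(n_nuc, n_spot, rel, rank_from_relative_area(rel, thresholds))


def segment_tunel_nucleus(img: np.ndarray, *, background_luminance_min: int = 220) -> np.ndarray:
    """Nucleus mask of a TUNEL image: everything darker than the slide background.

    Both the methyl-green counterstain and the DAB spots are darker than the
    clear background, so a single luminance cut recovers the whole nucleus.
    """
    return luminance_8bit(img) < background_luminance_min


def score_tunel_image(
    img: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    *,
    gray_window: tuple[int, int] = DEFAULT_GRAY_WINDOW,
    thresholds: tuple[float, float] = DEFAULT_AREA_THRESHOLDS,
    channel: str | int = "luminance",
) -> TunelScore:
    """Full single-cell pipeline: segment nucleus (if not given), detect, classify."""
    if nucleus_mask is None:
        nucleus_mask = segment_tunel_nucleus(img)
    spots = detect_spots(img, nucleus_mask, gray_window[0], gray_window[1], channel=channel)
    return classify_tunel(nucleus_mask, spots, thresholds)


def positivity_table(scores_by_condition: Mapping[str, Sequence[TunelScore]]) -> pd.DataFrame:
    """Per-condition positivity percentages (total / strong / moderate / weak).

    One row per condition with columns ``n_cells``, ``pct_total_positive``,
    ``pct_strong``, ``pct_moderate``, ``pct_weak``; the total is the sum of
    the three positive ranks.
    """
    if not scores_by_condition:
        raise ValueError("no conditions given")
    rows = []
    for condition, scores in scores_by_condition.items():
        if len(scores) == 0:
            raise ValueError(f"condition {condition!r} has no cells")
        n = len(scores)
        pct = {r: 100.0 * sum(s.rank == r for s in scores) / n for r in POSITIVE_RANKS}
        rows.append(
            {
                "condition": condition,
                "n_cells": n,
                "pct_total_positive": sum(pct.values()),
                "pct_strong": pct["strong"],
                "pct_moderate": pct["moderate"],
                "pct_weak": pct["weak"],
            }
        )
    return pd.DataFrame(rows)


def scores_to_frame(
    scores_by_condition: Mapping[str, Sequence[TunelScore]],
) -> pd.DataFrame:
    """Per-cell long table: (condition, cell_id, areas, relative area, rank)."""
    rows = []
    for condition, scores in scores_by_condition.items():
        for i, s in enumerate(scores):
            rows.append(
                {
                    "condition": condition,
                    "cell_id": i,
                    "nucleus_area_px": s.nucleus_area_px,
                    "spot_area_px": s.spot_area_px,
                    "relative_area_pct": s.relative_area_pct,
                    "rank": s.rank,
                }
            )
    return pd.DataFrame(rows)
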