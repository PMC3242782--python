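"""Population-level cytometry statistics.

Covers the group summaries (X, S, Md), the two-sample comparisons (two-sided
Student t when both samples pass a normality pre-test, Mann-Whitney U
otherwise, significance at alpha = 0.05), Feulgen-DNA C-class histograms
against a 2C calibration anchor, the Sc%-vs-AAR phenotype scatter diagram,
and mitotic/cell-death index ratios from morphology counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .densitometry import NucleusMeasurement

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: largest per-group n for which the Mann-Whitney null is evaluated exactly
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class GroupSummary:
    """n, arithmetic mean (X), sample SD (S, n-1 denominator) and median (Md)."""

    n: int
    mean: float
    sd: float
    median: float


def summarize(values: Sequence[float]) -> GroupSummary:
    """Summarize one group of measurements.

    NaNs (e.g. undefined AARs) are excluded; an empty or all-NaN input is an
    error.  The SD uses the n-1 denominator and is 0 for a single value; the
    median of an even n is the midpoint of the two central order statistics.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no values to summarize")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(int(arr.size), float(arr.mean()), sd, float(np.median(arr)))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample test result, significant when the two-sided P < alpha."""

    test: str  # "mann-whitney" or "t-two-sided"
    statistic: float
    p_two_sided: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


def _samples_look_normal(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk pre-test on each sample; constant or tiny samples fail it."""
    for s in (a, b):
        if s.size < 3 or np.ptp(s) == 0:
            return False
        if sps.shapiro(s).pvalue <= alpha:
            return False
    return True


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    force_test: str | None = None,
    *,
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """Two-sided two-sample comparison with automatic test selection.

    Unless ``force_test`` ("t" or "mann-whitney") is given, a Shapiro-Wilk
    pre-test at the same alpha chooses Student's t (both samples normal)
    versus Mann-Whitney.  The Mann-Whitney P is exact (full null
    distribution) for tie-free samples with min(n) <= 8 and uses the normal
    approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")

    if force_test is None:
        test = "t-two-sided" if _samples_look_normal(a, b, alpha) else "mann-whitney"
    elif force_test in ("t", "t-two-sided"):
        test = "t-two-sided"
    elif force_test in ("mw", "mann-whitney"):
        test = "mann-whitney"
    else:
        raise ValueError(f"unknown force_test {force_test!r}")

    if test == "t-two-sided":
        res = sps.ttest_ind(a, b, alternative="two-sided")
        return GroupComparison(test, float(res.statistic), float(res.pvalue), alpha)

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations identical: U is at its null mean, no evidence at all
        return GroupComparison(test, a.size * b.size / 2.0, 1.0, alpha)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return GroupComparison(test, float(res.statistic), float(res.pvalue), alpha)


# ---------------------------------------------------------------------------
# Feulgen-DNA C-class histograms


@dataclass(frozen=True)
class CClassHistogram:
    """DNA-content (C-value) class histogram anchored at a 2C reference.

    The ~2C class is centred on ``anchor_2C`` (the median Feulgen-DNA value
    of the calibration population); doubling classes ~4C, ~8C, ... follow.
    Bin edges sit at the geometric midpoints ``anchor * 2**(k +/- 0.5)``, and
    everything below the lower ~2C edge is the subdiploid "<2C" class.
    """

    anchor_2C: float
    labels: tuple[str, ...]
    edges: np.ndarray  # increasing edges; labels[0] ("<2C") is below edges[0]
    counts: np.ndarray
    fractions: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "count": self.counts, "fraction": self.fractions}
        )

    def fraction_of(self, label: str) -> float:
        return float(self.fractions[self.labels.index(label)])


def _class_index(values: np.ndarray, anchor: float) -> np.ndarray:
    """k such that value falls in class 2^k * 2C; -1 for '<2C'."""
    ratio = values / anchor
    k = np.floor(np.log2(ratio) + 0.5).astype(int)
    return np.where(ratio < 2**-0.5, -1, np.maximum(k, 0))


def c_class_label(k: int) -> str:
    return "<2C" if k < 0 else f"~{2 * 2**k}C"


def c_class_histogram(
    at_values: Sequence[float],
    reference: Sequence[float],
    *,
    min_reference_n: int = 10,
) -> CClassHistogram:
    """Bin Feulgen-DNA values (A_T) into C-value classes against a 2C reference.

    ``reference`` is the calibration population of known-diploid cells; its
    median anchors the ~2C class.  Every nucleus is assigned to exactly one
    class, so counts always sum to the population size.
    """
    at = np.asarray(at_values, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if at.size == 0 or ref.size == 0:
        raise ValueError("empty input")
    if ref.size < min_reference_n:
        raise ValueError(f"2C reference needs n >= {min_reference_n}, got {ref.size}")
    if np.any(at <= 0) or np.any(ref <= 0):
        raise ValueError("Feulgen-DNA values must be positive")

    anchor = float(np.median(ref))
    ks = _class_index(at, anchor)
    kmax = max(int(ks.max()), 0)
    labels = tuple(c_class_label(k) for k in range(-1, kmax + 1))
    counts = np.bincount(ks + 1, minlength=kmax + 2)
    edges = anchor * 2.0 ** (np.arange(0, kmax + 2) - 0.5)
    return CClassHistogram(anchor, labels, edges, counts, counts / at.size)


# ---------------------------------------------------------------------------
# scatter diagram


def scatter_diagram(
    measurements_by_group: Mapping[str, Sequence[NucleusMeasurement]],
    *,
    regions: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    ax=None,
):
    """Sc% vs AAR phenotype scatter diagram.

    Only AAR-defined nuclei are plotted (each point is one nucleus); groups
    get distinct colors, and an optional ``regions`` mapping of named
    phenotype zones (polygons in (Sc%, AAR) coordinates) is drawn as
    outlines.  No default region map ships: the published phenotype-zone
    geometry is schematic, not numeric, so zones are user-defined.

    Returns ``(table, ax)`` where table has columns (group, Sc_pct, AAR).
    """
    import matplotlib.pyplot as plt

    rows = []
    for group, ms in measurements_by_group.items():
        pts = [(m.sc_pct, m.aar) for m in ms if m.aar_defined]
        if not pts:
            logger.warning("group %r has no AAR-defined nuclei; omitted from scatter", group)
            continue
        rows.extend({"group": group, "Sc_pct": s, "AAR": r} for s, r in pts)
    table = pd.DataFrame(rows, columns=["group", "Sc_pct", "AAR"])

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for group, sub in table.groupby("group", sort=False):
        ax.scatter(sub["Sc_pct"], sub["AAR"], s=8, alpha=0.6, label=str(group))
    if regions:
        for name, poly in regions.items():
            xs, ys = zip(*(list(poly) + [poly[0]]))
            ax.plot(xs, ys, "--", linewidth=1)
            ax.annotate(name, (np.mean(xs), np.mean(ys)), fontsize=8, ha="center")
    ax.set_xlabel("Sc% (condensed chromatin area, % of nuclear area)")
    ax.set_ylabel("AAR (average absorption ratio)")
    if len(table):
        ax.legend(frameon=False)
    return table, ax


# ---------------------------------------------------------------------------
# morphology count ratios


@dataclass(frozen=True)
class CellClassCounts:
    """Visually scored cell-class counts from one preparation."""

    total_cells: int
    mitoses: int = 0
    abnormal_mitoses: int = 0
    micronucleated: int = 0
    giant_nuclei: int = 0
    apoptotic: int = 0
    multinucleation_death: int = 0

    def __post_init__(self) -> None:
        if self.total_cells < 1:
            raise ValueError("total_cells must be >= 1")
        for name in (
            "mitoses",
            "abnormal_mitoses",
            "micronucleated",
            "giant_nuclei",
            "apoptotic",
            "multinucleation_death",
        ):
            v = getattr(self, name)
            if v < 0 or v > self.total_cells:
                raise ValueError(f"{name}={v} must be in [0, total_cells]")


def index_ratios(counts: CellClassCounts) -> pd.Series:
    """Mitotic index and abnormality/death ratios as percentages of cells scored.

    The abnormal-mitosis fraction is additionally expressed as % of mitoses,
    reported as NaN when no mitoses were observed.
    """
    t = counts.total_cells
    out = {
        "mitotic_index_pct": 100.0 * counts.mitoses / t,
        "abnormal_mitoses_pct": 100.0 * counts.abnormal_mitoses / t,
        "micronucleated_pct": 100.0 * counts.micronucleated / t,
        "giant_nuclei_pct": 100.0 * counts.giant_nuclei / t,
        "apoptotic_pct": 100.0 * counts.apoptotic / t,
        "multinucleation_death_pct": 100.0 * counts.multinucleation_death / t,
        "abnormal_pct_of_mitoses": (
            100.0 * counts.abnormal_mitoses / counts.mitoses if counts.mitoses > 0 else math.nan
        ),
    }
    return pd.Series(out)
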