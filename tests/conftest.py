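"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they check:
densitometry is re-derived with a plain per-pixel Python loop, and the
Mann-Whitney exact P with a full enumeration of rank assignments.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from feulgen.image import AbsorbanceImage


# ---------------------------------------------------------------------------
# densitometry oracle: naive per-pixel loop


def brute_force_measure(values, mask_bool, cutoff, pixel_pitch_um):
    """Per-pixel loop re-deriving every karyometric parameter.

    Sums are exactly rounded (math.fsum), so the result does not depend on
    the order pixels are visited in.
    """
    in_mask, condensed = [], []
    n_rows, n_cols = np.asarray(values).shape
    for r in range(n_rows):
        for c in range(n_cols):
            if mask_bool[r][c]:
                od = float(values[r][c])
                in_mask.append(od)
                if od > cutoff:
                    condensed.append(od)
    assert in_mask, "oracle needs a non-empty mask"
    px_area = pixel_pitch_um * pixel_pitch_um
    a_t = math.fsum(in_mask)
    a_c = math.fsum(condensed)
    s_t = len(in_mask) * px_area
    s_c = len(condensed) * px_area
    return {
        "a_t": a_t,
        "a_c": a_c,
        "ac_pct": 100.0 * a_c / a_t if a_t > 0 else 0.0,
        "s_t_um2": s_t,
        "s_c_um2": s_c,
        "sc_pct": 100.0 * s_c / s_t,
        "aar": (a_c / s_c) / (a_t / s_t) if condensed else float("nan"),
        "n_pixels": len(in_mask),
        "n_condensed_pixels": len(condensed),
    }


def random_absorbance_image(rng, max_side=32, max_od=0.4, pitch=0.5):
    """Random small absorbance image plus a random non-empty mask."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    values = rng.uniform(0.0, max_od, size=(h, w))
    mask = rng.random((h, w)) < rng.uniform(0.2, 0.9)
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    return AbsorbanceImage(values, pixel_pitch_um=pitch, source="synthetic"), mask


# ---------------------------------------------------------------------------
# Mann-Whitney oracle: full enumeration of rank assignments


@lru_cache(maxsize=None)
def _mw_null_distribution(n_a: int, n_b: int):
    """Counts of each U value over all C(n_a+n_b, n_a) rank assignments."""
    total = n_a + n_b
    offset = n_a * (n_a + 1) // 2
    counts: dict[int, int] = {}
    for positions in itertools.combinations(range(total), n_a):
        u = sum(positions) + n_a - offset  # ranks are positions+1
        counts[u] = counts.get(u, 0) + 1
    return counts


def mann_whitney_exact_enumeration(a, b) -> tuple[float, float]:
    """(U of the first sample, exact two-sided P) for tie-free samples.

    U counts pairs with x > y; the two-sided P doubles the smaller tail
    (point mass included) and caps at 1 — the standard exact definition.
    """
    a, b = list(a), list(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    assert len(set(a) | set(b)) == len(a) + len(b), "oracle requires tie-free data"
    null = _mw_null_distribution(len(a), len(b))
    n_total = math.comb(len(a) + len(b), len(a))
    cdf = sum(c for u, c in null.items() if u <= u_obs) / n_total
    sf = sum(c for u, c in null.items() if u >= u_obs) / n_total
    return float(u_obs), min(1.0, 2.0 * min(cdf, sf))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
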