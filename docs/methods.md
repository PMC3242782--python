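# Methods

## Measurement model

The pipeline reproduces scanning-microspectrophotometry karyometry on a
discrete absorbance grid. An `AbsorbanceImage` holds per-pixel optical
densities (dimensionless, ≥ 0) with a physical pixel pitch, 0.5 µm by
default, so one pixel covers 0.25 µm². Instruments that record intensity
rather than absorbance are handled by Beer-Lambert conversion
`OD = log10(I_white / I)`; intensities at or below a floor of 1 count are
clipped to the floor and flagged, since the log diverges and the detector
is effectively saturated in absorbance there.

Segmentation follows the background rule: grid points with OD **≤ 0.020**
are background and removed; the surviving pixels are grouped into
8-connected components, and components under 50 px (configurable) are
discarded as debris. This replaces the instrument operator's manual framing
of individual nuclei; touching nuclei are not split (no watershed), which
is a known limitation for dense fields — the synthetic substrate renders
one nucleus per image, so the limitation is not exercised in the shipped
tests.

Per nucleus, with condensed chromatin defined as in-mask pixels with OD
**strictly above 0.100**:

* `A_T = Σ OD` over the mask, `S_T = |mask| · pitch²`;
* `A_C`, `S_C` over the condensed subset; `Ac% = 100·A_C/A_T`,
  `Sc% = 100·S_C/S_T`;
* `AAR = (A_C/S_C)/(A_T/S_T)`, reported as NaN when `S_C = 0` and excluded
  from group statistics — the ratio is undefined for a nucleus with no
  condensed pixels.

The inequality sides deserve a note: the background rule is "no higher
than", hence inclusive (`≤ 0.020` removed), while the condensed cutoff side
is a convention choice; this package uses strict `> 0.100` and exposes the
cutoff as a parameter. Integrated absorbances are computed as
exactly-rounded floating-point sums (`math.fsum`), which makes every
karyometric parameter a pure histogram functional: invariant to pixel
order, and exactly equal to a naive per-pixel accumulation. That is what
lets the test suite demand bit-exact agreement with an independent
brute-force oracle rather than a tolerance.

## Group statistics

Summaries report n, arithmetic mean (X), sample SD (S, n−1 denominator,
0 for n = 1) and median (Md, midpoint rule for even n). Two-sample
comparisons are two-sided at α = 0.05. Test selection mimics the
conventional practice of pre-testing normality: Shapiro-Wilk on each sample
at the same α, Student's t (pooled variance) when both pass, Mann-Whitney U
otherwise; the choice can be forced. The Mann-Whitney P is exact — the full
null distribution of U — for tie-free samples with min(n) ≤ 8, and the
normal approximation with continuity and tie correction otherwise (both via
scipy). Two all-identical samples are answered with U at its null mean and
P = 1 directly, since the variance of the tie-corrected approximation
degenerates. No multiple-testing correction is applied anywhere.

## C-value classes

DNA-content classes are anchored on a diploid calibration population
(the experimental role human lymphocytes play). The anchor is the
**median** of the calibration A_T values — a robust choice preferred over
the literal smallest control values, which an outlier would corrupt. Class
`2^k · 2C` spans `[anchor·2^(k−0.5), anchor·2^(k+0.5))`, i.e. bin edges sit
at geometric midpoints between doubling classes, with the lower ~2C edge
closed; everything below `anchor·2^(−0.5)` is the subdiploid `<2C` class.
Every value maps to exactly one class, so counts always sum to the
population size, and labels are invariant under joint rescaling of values
and reference (arbitrary absorbance units cancel).

## TUNEL scoring

Spot pixels are in-nucleus pixels whose 8-bit gray value lies in
**[60, 100] inclusive**. For color input the gray value is BT.601 luminance
by default; the camera channel is selectable because which channel the
window was historically defined on is instrument-specific. Ranks follow the
relative spot area exactly: 0 → negative, (0, 5)% → weak, [5, 50)% →
moderate, ≥ 50% → strong (closed lower bounds at 5 and 50). Scoring is
area-based by design; mean-gray scoring is deliberately not implemented
because the DAB reaction product does not obey the Beer-Lambert law, so
mean gray is not a valid quantitative readout for this assay.

## Synthetic-nucleus generator

The generator is the study substrate, not a fixture. A nucleus is an
area-preserving ellipse (axis ratio uniform in [0.75, 1], orientation
uniform — the eccentricity range is a modeling choice, since only areas,
not shapes, are constrained by the phenomenology being emulated). In-mask
pixels are partitioned by thresholding a Gaussian random field smoothed to
a correlation length of `focus_scale_px` (default 3 px) at the quantile
that yields the requested condensed-area fraction — spatially coherent
condensed blobs with exact-by-construction area control (realized fraction
= round(f·n)/n). Compartment ODs default to 0.05 (diffuse) and 0.30
(condensed), straddling the 0.100 cutoff; i.i.d. Gaussian noise
(sd 0.01 OD) is added and values are clipped at 0 because absorbance is
non-negative. When a target IOD is requested, in-mask ODs are rescaled
after clipping so the sum matches the target exactly; this is how ploidy
classes are simulated. Masks too small to carry the request raise a
degenerate-geometry error.

Population presets draw per-nucleus condensed fractions logit-normally
(sd 0.5 on the log-odds scale), so the population **median** fraction
equals the preset value exactly and values stay in (0, 1): control median
0.60, decondensed 0.40 — the direction and rough magnitude of the Sc% shift
seen when HDAC-inhibited cells are compared with untreated controls. The
paper-style dispersion of derived quantities is only reported, not
generative, so the logit-normal spread is an explicit free choice. Radii
are normal (mean 36 px, sd 3, floored at 30 px ≈ 1000 µm² at 0.5 µm pitch);
the calibration guarantees of the measurement path (realized fraction
within 2 points, measured Sc% within 5 points of truth) are stated for
radius ≥ 30 px, where pixel granularity and edge effects are negligible,
so the presets live in that regime even though real HeLa nuclear areas are
several-fold smaller. TUNEL cells are rendered as flat-tone RGB: background
(245,245,245), methyl-green nucleus (150,200,160) → luminance 180, DAB spot
(120,70,40) → luminance 82, validated at generation time to fall inside
(spots) or outside (everything else) the detection window, so a noise-free
round trip through segmentation → window detection → area ranking recovers
the generated rank exactly. Per-condition TUNEL populations mix a Bernoulli
positivity probability with a Beta coverage distribution (control: 6%
positive, Beta(1.2, 8); treated: 35%, Beta(1.5, 4)) — chosen to produce the
direction of a cytotoxic dose response, not any particular measured table.

What the generator does **not** emulate: optics (PSF, glare, focus),
stain-kinetics variability, touching/overlapping nuclei, mitotic figures,
micronuclei, apoptotic-body morphology, and staining gradients. Passing
tests therefore demonstrate correctness of the measurement and statistics
machinery under known ground truth, not robustness to real-slide artifacts.

## Determinism and numerics

All randomness flows from `numpy.random.default_rng` seeds; population
generators spawn per-nucleus child seeds from the population seed, and the
pipeline derives per-condition seeds from the run seed, so any sub-result
is reproducible in isolation. Identical config + seed gives byte-identical
CSVs (fixed column order, fixed `%.10g` float formatting, `\n` line
endings). Ties in the random-field quantile threshold are broken by stable
sort order; with continuous fields they do not occur in practice.

## Problem sizes

The shipped tests and the acceptance script use 200 nuclei per karyometric
condition and 1000 TUNEL cells per condition — the per-condition sample
sizes of the measurement protocol being modeled — with smaller populations
in unit tests where only mechanics are exercised.
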