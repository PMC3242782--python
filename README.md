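# feulgen

Image cytometry of Feulgen-stained nuclei: per-nucleus densitometry,
chromatin-texture statistics, DNA-ploidy (C-class) histograms, TUNEL
dark-spot scoring, and the group statistics that go with them — plus a
seeded synthetic-nucleus generator so the whole pipeline is testable
without microscope data.

## The scientific problem

The Feulgen reaction stains DNA stoichiometrically, so the integrated
optical density of a stained nucleus is proportional to its DNA content,
and the spatial distribution of absorbance carries chromatin-texture
information. Treatments that inhibit histone deacetylases (e.g. valproic
acid, trichostatin A) decondense chromatin; scanning microspectrophotometry
quantifies that remodeling per nucleus. For a nucleus measured on an
absorbance grid (pixel pitch 0.5 µm; grid points with OD ≤ 0.020 are
background and removed), with a condensed-chromatin cutoff of OD 0.100:

- **A_T** — total integrated absorbance (the Feulgen-DNA value / IOD),
- **A_C** — integrated absorbance over the cutoff, **Ac% = 100·A_C/A_T**,
- **S_T** — nuclear area (µm²), **S_C** — area above the cutoff,
  **Sc% = 100·S_C/S_T** (relative condensed-chromatin area),
- **AAR = (A_C/S_C)/(A_T/S_T)** — the average absorption ratio: how many
  times the mean absorbance of condensed chromatin exceeds that of the
  whole nucleus. AAR ≥ 1 whenever defined, since condensed pixels are the
  top-OD subset; chromatin decondensation shows up as Sc% falling while
  AAR rises.

Populations are compared with two-sided Student t (when both samples pass a
normality pre-test) or Mann-Whitney U tests at α = 0.05, summarized as
X (mean), S (SD), Md (median). DNA content is binned into C-value classes
(~2C, ~4C, ~8C, <2C) against the median Feulgen-DNA value of a diploid
calibration population. TUNEL positivity (fragmented DNA revealed as dark
DAB spots) is scored by the fraction of the nuclear area covered by pixels
in an 8-bit gray window of [60, 100]: negative (0), weak (<5%), moderate
(5–49%), strong (≥50%).

## Worked example

```python
from feulgen import NucleusSimParams, generate_nucleus, measure_image

params = NucleusSimParams(nucleus_radius_px=32, condensed_fraction=0.60, seed=3)
img, mask, truth = generate_nucleus(params)
m = max(measure_image(img), key=lambda m: m.n_pixels)
print(f"true condensed fraction: {truth.true_condensed_fraction:.4f}")
print(f"A_T = {m.a_t:.2f}   S_T = {m.s_t_um2:.2f} um^2")
print(f"Sc% = {m.sc_pct:.2f}   Ac% = {m.ac_pct:.2f}   AAR = {m.aar:.3f}")
```

prints

```
true condensed fraction: 0.5999
A_T = 643.52   S_T = 804.25 um^2
Sc% = 60.02   Ac% = 89.99   AAR = 1.499
```

A nucleus generated with 60% of its area as condensed foci is measured back
at Sc% = 60.02 — the full segmentation + densitometry path recovers the
generator's ground truth to within pixel granularity. AAR ≈ 1.5 because the
condensed compartment (mean OD 0.30) absorbs 1.5× the nuclear average.

The same flow from the shell:

```sh
feulgen simulate nuclei --preset control --n 200 --seed 7 --out sim/
feulgen measure --input sim/ --out measurements.csv
feulgen report --out results/ --seed 7      # full two-condition pipeline
```

`report` simulates a control and a decondensed condition (200 nuclei each,
plus TUNEL conditions with 1000 cells each), measures every nucleus through
the image pipeline, and writes per-nucleus tables, group summaries,
comparison tests, C-class histograms, the Sc%-vs-AAR scatter plot and a
run manifest. Runs are byte-identical given the same config and seed.

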