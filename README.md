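# chemoassay

Quantification pipeline for *in vitro* biofilm disinfection assays. The
target experiment challenges biofilms of standardized thickness (grown
recessed to a nominal 250 µm) with an antimicrobial irrigant such as
sodium hypochlorite in a time × volume factorial design, and asks how much
biofilm was removed and how the remaining biofilm's architecture changed.
`chemoassay` implements the measurement side of that experiment for three
instrument modalities, plus the factorial statistics, plus synthetic
phantom generators so the whole chain is testable end to end with known
ground truth.

## What it computes

**OCT layer metrics** (`chemoassay.oct_quant`). A B-scan is segmented by
3-class multilevel Otsu thresholding (exhaustive maximization of the
between-class variance σ²_B over ordered threshold pairs, lexicographic
tie-break) into background, a low-intensity *disrupted* stratum, and a
high-intensity *coherent* stratum attached to the substrate. Per-column
pixel counts × pixel pitch give layer thickness profiles h(x), and a
pre/post-treatment pair yields the two outcome measures

- dissolution (%) = 100 · (h̄ᶜᵒʰ_pre − h̄ᶜᵒʰ_post) / h̄ᶜᵒʰ_pre
- disruption (%) = 100 · (h̄ᵈⁱˢ_post − h̄ᵈⁱˢ_pre) / (h̄ᶜᵒʰ_pre + h̄ᵈⁱˢ_pre)

**Viscoelastic decomposition** (`chemoassay.llct_visco`). A low load
compression test holds a biofilm at 20% strain and records the stress
decay σ(t) over 100 s. The package computes the percentage stress
relaxation R = 100·(σ(0) − σ(100))/σ(0) and fits a four-arm generalized
Maxwell (Prony) model

E(t) = σ(t)/ε = Σᵢ Eᵢ·exp(−t/τᵢ),  i = 1…4,  Eᵢ ≥ 0,

by variable projection (bounded least squares on log τ, non-negative
linear least squares for the Eᵢ, multi-start). Each arm is allocated to a
biofilm constituent by its time constant — free water (τ < 0.5 s), bound
water (0.5–3 s), EPS (3–100 s), bacteria (> 100 s) — and the *relative
importance* of a constituent is 100·Eᵢ/ΣⱼEⱼ, the arm's share of the total
stiffness at t = 0. Evaporation drift is removed by subtracting a blank
reference trace.

**Confocal biovolume fractions** (`chemoassay.clsm_quant`). COMSTAT-style:
each channel of a three-channel stack (green = live bacteria, red = dead
bacteria, blue = EPS) is thresholded with a global Otsu cut (guarded by a
minimum-contrast test so signal-free channels count as empty), biovolume =
foreground voxels × voxel volume, and each component is reported as a
percentage of total biomass.

**Factorial statistics** (`chemoassay.stats_report`). Two-way fixed-effects
ANOVA with interaction (Type III SS, sum-to-zero contrasts), Tukey HSD
contrasts on the 3-level time factor using the factorial residual mean
square, SPSS-style simple effects against the pooled omnibus error term,
and mean ± SD summary tables.

**Phantoms** (`chemoassay.synthetic_data`). Generators for all three
modalities with attached ground truth: layered speckled B-scan pairs,
Prony-series relaxation curves with noise and evaporation drift, and
three-channel stacks with prescribed biomass fractions.
`generate_study()` writes a full factorial study to disk with a manifest,
reproducible from a single seed.

## Worked example

Generate a 3 × 2 factorial phantom study (n = 10 per cell), run the OCT
pipeline over every sample, and analyse the dissolution outcome:

```python
from pathlib import Path
from chemoassay import synthetic_data as sd, pipeline, stats_report as sr

groups = [
    sd.GroupDesign(time_s=t, volume_ul=v, n=10,
                   true_dissolution_pct={60: 20.0, 120: 35.0, 300: 80.0}[t]
                                        + (5.0 if v == 40 else 0.0),
                   true_disruption_pct={60: 25.0, 120: 45.0, 300: 70.0}[t],
                   between_sample_sd=12.0)
    for t in (60, 120, 300) for v in (20, 40)
]
sd.generate_study(groups, Path("study"), seed=17)
oct_res = pipeline.analyze_oct_study(pipeline.load_manifest(Path("study")))
ds = sr.FactorialDataset(oct_res)
print(sr.two_way_anova(ds, "dissolution_pct").round(4))
print(sr.table1_markdown(ds, ["dissolution_pct", "disruption_pct"]))
```

prints

```
                 sum_sq    df     mean_sq         F       p
Time         39055.0066   2.0  19527.5033  117.7087  0.0000
Volume         485.5155   1.0    485.5155    2.9266  0.0929
Time:Volume    712.6695   2.0    356.3347    2.1479  0.1266
Residual      8958.4266  54.0    165.8968       NaN     NaN

| time (s) | dissolution_pct mean | dissolution_pct SD | disruption_pct mean | disruption_pct SD |
|---|---|---|---|---|
| 60 | 20.3 | 13.4 | 25.0 | 14.5 |
| 120 | 41.3 | 13.9 | 45.5 | 16.3 |
| 300 | 81.8 | 12.8 | 68.8 | 10.7 |
```

The exposure-time effect injected into the phantoms (20/35/80% mean
dissolution) dominates the ANOVA (P < 10⁻⁴); the small +5-point volume
effect is not resolved at n = 10 (P ≈ 0.09); and the recovered per-time
group means (20.3 / 41.3 / 81.8%) track the generative truths through the
full image chain — generation, TIFF round-trip, multilevel thresholding,
height profiling and the outcome ratios.

A CLI mirrors the library: `chemoassay simulate | oct | llct | clsm |
stats` (see `chemoassay --help`).

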