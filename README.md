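# phoskit

Quantitative analysis of phosphene drawings from epiretinal prostheses.

Users of epiretinal implants (e.g. the Argus II, a 6×10 grid of 200 µm
electrodes spaced 575 µm apart) perceive electrically elicited flashes of
light — *phosphenes* — which they can trace on a touchscreen. Because
epiretinal electrodes also stimulate passing retinal ganglion cell axons,
phosphenes are typically elongated along the underlying nerve-fiber bundle.
`phoskit` is a pipeline for researchers analyzing such drawings. It answers
two questions about two-point perception:

1. **Linear summation** — is each shape descriptor of a paired-electrode
   phosphene proportional to the *sum* of the corresponding
   single-electrode descriptors? (Fitted as an intercept-free regression;
   a slope β with 0.5 < β < 1 means paired percepts are larger than the
   average but smaller than the sum of their parts.)
2. **Axon-map prediction of phosphene count** — does the probability of
   seeing *two* phosphenes track the **between-axon** distance (nasal
   electrode center → the temporal electrode's closest bundle) rather than
   the **along-axon** distance (arc length along that bundle between the
   two foot points)? Decided by AIC/BIC comparison of the two model
   families.

## What's inside

| module | role |
| --- | --- |
| `phoskit.io` | trial manifests (CSV), binary drawing masks (PNG), implant geometry (YAML/JSON), pixel↔degree conversion, spec cleaning |
| `phoskit.shapes` | connected regions; moment-based descriptors `M_ij = Σ x^i y^j I(x,y)`: area `M00`, centroid `(M10/M00, M01/M00)`, axis lengths `4√λ` from the second-moment covariance, border-polyline perimeter |
| `phoskit.axon` | simulated nerve-fiber-bundle map `φ(r) = φ0 + b(r−r0)^c` (fovea-origin retinal frame, 280 µm/deg), electrode–fovea distance, between-/along-axon decomposition |
| `phoskit.normalize` | standard-pulse (2×Th, 20 Hz) normalization, trial averaging, 2.5 SD outlier removal, power transforms (area^⅓, others^½), covariate z-scoring |
| `phoskit.stats` | standardized OLS + partial correlations, random-intercept mixed models, Welch's t, VIF, Bonferroni, AIC/BIC model comparison, summation regression |
| `phoskit.synth` | seeded synthetic cohorts with planted effects (summation gain, between-axon logistic for phosphene count) |
| `phoskit.analysis` | end-to-end cohort analysis producing the tabled results |

## Worked example

```python
from phoskit.synth import CohortConfig, generate_cohort
from phoskit.analysis import run_analysis

cfg = CohortConfig(n_electrodes=6, n_pairs=8, trials_per_condition=3)
cohort = generate_cohort(cfg, seed=7)   # 3 participants, planted gain 0.65
res = run_analysis(cohort)

print(f"drawings: {len(cohort.trials)}, data points: "
      f"{len(res.single_points)} single + {len(res.paired_points)} paired")
print(f"summation gain (area, raw scale): {res.summation_gain['area']:.3f}")
for desc, fit in res.summation_fits.items():
    p = fit.predictors[0]
    print(f"  {desc:>9}: beta = {p.beta:.3f}, r = {p.partial_r:.3f}{p.stars}")
cmp_all = res.model_comparisons["all"]
print(f"phosphene count: AIC(along) - AIC(between) = {cmp_all.delta_aic:.1f}"
      f" -> {cmp_all.verdict_aic}")
```

prints

```
drawings: 756, data points: 169 single + 71 paired
summation gain (area, raw scale): 0.643
       area: beta = 0.554, r = 0.968***
  perimeter: beta = 0.627, r = 0.948***
      major: beta = 0.641, r = 0.948***
      minor: beta = 0.562, r = 0.784***
phosphene count: AIC(along) - AIC(between) = 16.0 -> strong evidence against model A
```

Reading it: the generator planted a summation gain of 0.65 — paired
descriptor sums are 65% of the single-electrode sums — and the pipeline
recovers 0.643 on the raw area scale. The per-descriptor β values are the
table-style slopes on the power-transformed scale (hence compressed below
the gain, but inside the (0.5, 1) "more than the average, less than the
sum" band). The phosphene-count model built on between-axon distance beats
the along-axon model by 16 AIC points, i.e. strong evidence that the count
is driven by the distance between bundles — the axon-map signature.

Real cohorts are ingested the same way: a manifest CSV
(`participant,electrode1,electrode2,amplitude_x_th,frequency_hz,trial,mask_path,viewing_distance_cm`),
single-channel PNG masks, and per-participant implant geometry YAML; see
`phoskit.io.load_manifest` and the `phoskit analyze` CLI. `phoskit
simulate --seed 3 --out data/` writes a complete synthetic dataset in that
exact on-disk format.

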