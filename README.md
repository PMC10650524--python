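# stomapattern

Spatial statistics of stomatal point patterns on leaf surfaces.

Stomata — the pores that control a leaf's gas exchange — are usually counted
as a single density number under the assumption that they are spread
uniformly over the lamina. This package quantifies where that assumption
breaks: it takes tables of stomatal center coordinates measured in
rectangular microscope fields of view (by default 1.2 mm × 0.9 mm) and
computes, per window,

* **SD** — stomatal density (mm⁻²),
* **MNND** — mean nearest-neighbor distance between stomatal centers (μm),
* **SAI** — the Clark–Evans stomatal aggregation index

  SAI = MNND / r̄_E,  with r̄_E = 1 / (2 √ρ)

  the expected nearest-neighbor distance under complete spatial randomness
  (CSR) at the observed density ρ. SAI < 1 indicates clustering, SAI = 1
  randomness, SAI > 1 regular spacing (spatial repulsion between stomata);
  the asymptotic maximum is 2·√(2/√3) ≈ 2.1491 at hexagonal packing.

Across windows it fits the log–log scaling of density on spacing by reduced
major axis (RMA),

  ln SD = a + b · ln MNND,  |b| = s_y / s_x,

with percentile bootstrap confidence intervals (3000 pair resamples by
default). Under CSR the line is exact with b = −2 and
a = ln(10⁶/4) ≈ 12.43 (SD in mm⁻², MNND in μm); departures of the fitted
CIs from those anchors are evidence of non-random stomatal arrangement, and
the fitted line lets SD be estimated quickly from the much-easier-to-measure
MNND. Two species (or any two groups of windows) are compared by the
bootstrap difference test: replicate-wise differences D of intercept and
slope, with a 95% CI of D containing 0 meaning no significant difference.

Within-leaf contrasts across lamina sections (layers apex → base, positions
midrib vs. margin) use a sign-flip permutation test on paired per-leaf
differences with compact letter displays — a self-contained stand-in for a
mixed-effects model with leaf as a random effect.

Because real coordinate tables come from hand-annotated micrographs, the
package also ships point-process simulators (CSR, Matérn type-II hard core,
Thomas cluster, sequential inhibition) and a full two-species synthetic
study generator (16 leaves × 6 sections + 16 leaves × 8 sections =
224 windows) so every stage of the pipeline is testable without any data
download. See `docs/methods.md` for the statistical details and design
choices.

## Worked example

```python
import numpy as np
import stomapattern as sp

# simulate the built-in two-species study (hard-core repulsion, h = 25 μm)
patterns, manifest = sp.generate_study(seed=42)
stats = sp.window_stats_table(patterns)
print(len(patterns), stats.sai.min().round(3), stats.sai.max().round(3))
# 224 1.181 1.407

sub = stats[stats.species == "species_A"]
fit = sp.bootstrap_rma(np.log(sub.mnnd), np.log(sub.sd),
                       n_boot=3000, seed=42)
print("slope %.3f CI (%.3f, %.3f)" % (fit.slope, *fit.ci_slope))
print("intercept %.3f CI (%.3f, %.3f)" % (fit.intercept, *fit.ci_intercept))
# slope -2.878 CI (-3.051, -2.718)
# intercept 16.169 CI (15.577, 16.810)
print("predict SD at MNND 35um: %.1f" % fit.predict_density(35.0))
# predict SD at MNND 35um: 378.8
```

All 224 windows are classified "regular" (SAI between 1.18 and 1.41): the
hard-core repulsion inflates every nearest-neighbor distance above the CSR
expectation. The RMA slope CI (−3.05, −2.72) excludes −2 and the intercept
CI excludes 12.43 — exactly the signature of non-random, regularly spaced
stomata — while the fit is still tight enough (r² ≈ 0.93) for the line to
predict density from spacing. Comparing the two simulated species:

```python
b = stats[stats.species == "species_B"]
cmp = sp.compare_groups(np.log(sub.mnnd), np.log(sub.sd),
                        np.log(b.mnnd), np.log(b.sd), seed=42)
print("D intercept CI (%.3f, %.3f) -> %s"
      % (*cmp.ci_d_intercept, cmp.verdict_intercept))
# D intercept CI (-0.690, 0.758) -> no significant difference
```

Both species follow the same scaling law, so the difference CIs straddle 0.

The same analysis runs from the shell on any coordinate CSV:

```
stomapattern simulate --seed 42 --points coords.csv --windows windows.csv
stomapattern run --points coords.csv --windows windows.csv --outdir out/
```

producing `window_stats.csv`, `section_summary.csv`, per-species
`scaling_*.json`, `comparison.json`, letter displays and a run log.

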