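# vwmtradeoff

Analysis toolkit for the voluntary **quality/quantity trade-off in visual
working memory (VWM)**: does an individual's storage capacity predict how
well they can trade memory *precision* against memory *number* when the
task demands it?

The package is aimed at visual-psychophysics researchers running paired
change-detection + continuous-report ("colour wheel") sessions. It covers
the full analysis chain:

- **Mixture-model decomposition** of signed recall errors. The standard
  model is `f(e) = (1−G)·vM(e; 0, κ) + G/360`: a von Mises memory
  component (precision reported as circular SD, in degrees) plus a uniform
  guess component; P = 1 − G is the retention probability. A swap model
  adds a non-target intrusion component with weight B. Fitting is plain
  multi-start bounded maximum likelihood with a brute-force grid oracle
  for validation.
- **Cowan's K** capacity estimation from single-probe change detection,
  `K = N(H − F)`, with median-split grouping.
- **Trade-off indices** per participant:
  `SDT = (SD_low − SD_high)/SD_low`, `PT = (P_low − P_high)/P_low`,
  `GT = SDT + PT`.
- **Inference**: mixed-design ANOVA (condition × capacity group) with η²,
  paired t with Cohen's d and the JZS default Bayes factor
  (Cauchy prior scale √2/2), and one-tailed Pearson correlations between
  K and the trade-off indices.
- **Critical-value classifier** for the published literature: predict a
  voluntary trade-off iff exposure duration per item ≥ 100 ms/item, with
  a packaged 25-experiment summary table.
- A **synthetic-cohort generator** with known ground truth, so every
  stage is validated by parameter recovery. Long-exposure cohorts link
  capacity to the true trade-off (`GT_true = max(0, α(K − K0))`);
  short-exposure cohorts have no linkage.

## Worked example

```bash
vwmtradeoff simulate --preset exp1 --seed 5 --out data/
vwmtradeoff analyze --data data/ --out report.json --n-starts 4
vwmtradeoff table1
```

prints

```
wrote 2600 change-detection and 14560 recall trials for 26 participants to data
analyzed 26 participants; K-GT correlation r = 0.455 (one-tailed p = 0.0098); report at report.json
23 of 25 experiments consistent with the critical-value rule
```

The simulated long-exposure cohort (26 participants, 100 change-detection
trials at set size 6, 280 recall trials per precision condition, capacity
linked to the true trade-off with slope 0.15 above 1.5 items) yields a
significant positive one-tailed correlation between capacity K and the
general trade-off index GT — the signature of capacity-limited voluntary
resource allocation. Group mean K values for this seed are 1.92 (low) and
3.35 (high). `report.json` carries per-participant summaries (K, group,
per-condition SD/P fits, SDT/PT/GT), the group-level ANOVA / paired-test /
Bayes-factor block, the K-correlations, and the critical-value block
(125 ms/item → trade-off predicted). With `--preset exp2` (200 ms
exposure, no capacity linkage) the same pipeline reports a null
correlation. The last line checks the packaged literature table against
the 100 ms/item rule: 23 of the 25 encoded experiments are consistent.

The same machinery is available as a library:

```python
import vwmtradeoff as v

trials = v.simulate_recall(0.6, 20.0, 0.0, 200, "low_precision", seed=1)
errors = v.simulate.signed_errors(trials)
fit = v.fit_mixture(errors)          # -> G, kappa, SD (deg), P, loglik
```

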