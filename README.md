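# circaweld

Cross-platform concatenation and rhythm analysis of circadian gene-expression
time series.

## The problem

Circadian time-course experiments are expensive, so individual datasets are
short — often a single 24-h cycle sampled every 3 h. When the same biological
system has been profiled on two platforms over *overlapping* windows (e.g. a
microarray series covering 0–24 h and an RNA-seq series covering 12–42 h
after synchronization), welding the two series together yields almost two
full circadian cycles and markedly more robust rhythm calls — provided the
platforms' very different value distributions are first made comparable.
`circaweld` implements that workflow for computational chronobiologists:

1. **Preprocess** each platform: collapse features to genes (highest-mean
   feature wins), TMM-normalize counts, transform to CPM, and filter
   low-expressed genes (mean ≥ 0.5 CPM for counts, mean log2 intensity ≥ 3
   for arrays, with counts renormalized on the retained genes).
2. **Harmonize**: Training Distribution Matching (TDM) maps the log2-CPM
   distribution onto the bounded log2-intensity range; each platform is then
   normalized per gene, on the linear scale, to its mean over the shared
   time window (12–24 h), and the series are concatenated with the
   overlapping time points treated as replicates.
3. **Detect rhythms** by harmonic (cosinor) regression at fixed period
   *T* = 24 h:

       y(t) = M + a·cos(ωt) + b·sin(ωt),  ω = 2π/T,
       A = √(a² + b²),  r_A = A/M,  φ = (T/2π)·atan2(b, a) mod T,

   with an F test (2, n−3 df) against the flat model, Benjamini–Hochberg
   adjustment, and the significance rule *q* < 0.05 ∧ *r_A* ≥ 0.1.
4. **Compare platforms** with the mean per-time-point Pearson correlation of
   expression, the Jammalamadaka–SenGupta circular correlation of phases,
   and the Pearson correlation of relative amplitudes.
5. **Phase Set Enrichment Analysis (PSEA)**: per gene set, the Kuiper test
   of its rhythmic members' phases (rounded to the full hour) against a
   uniform background; sets with < 5 rhythmic members are excluded, and
   enrichment requires *q* < 0.05.

A first-class synthetic-data generator emulates the two platform designs
with known per-gene truth, so the whole pipeline is testable end to end
without any downloads.

## Worked example

```python
import circaweld as cw
from circaweld.pipeline import analyze_two_platforms

truth = cw.simulate_truth(10000, frac_rhythmic=0.2,
                          relamp_range=(0.2, 0.6), seed=1)
intensity = cw.render_intensity(truth, seed=2)   # 9 samples, 0-24 h
counts = cw.render_counts(truth, seed=3)         # 11 samples, 12-42 h

analysis = analyze_two_platforms(intensity, counts)
fits = analysis["fits"]["concatenated"]
print(cw.recovery_report(truth, fits))
```

prints

```
{'n_true_rhythmic': 2000, 'n_significant': 1883, 'n_true_positive': 1822,
 'sensitivity': 0.911, 'fdr': 0.0323951141795008,
 'median_phase_error_h': 0.38909811047106935,
 'median_relamp_rel_error': 0.09102863984723752}
```

i.e. of the 2,000 truly rhythmic genes the concatenated 20-sample series
recovers 91% at a realized false-discovery rate of 3.2%, with the fitted
peak phase off by a median of 0.39 h. Fitting one gene directly gives a
statsmodels-style results object:

```python
res = cw.HarmonicRegression(
    analysis["concatenated"].matrix.values.iloc[0],
    analysis["concatenated"].matrix.sample_time_h,
).fit()
print(res.summary())
```

The command line mirrors the library: `circaweld simulate | preprocess |
harmonize | rhythm | corr | psea | annotate`, plus `circaweld run --config
config.yaml` for the full workflow with a manifest and byte-reproducible
outputs.

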