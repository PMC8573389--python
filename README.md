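# megfc

Frequency-resolved functional-connectivity and graph-theory analysis of
multichannel MEG-like recordings around absence-seizure termination — with a
synthetic-data generator that provides ground truth for every stage.

## Who this is for

Researchers analysing spike-and-wave discharges (SWDs, the ~3 Hz signature of
childhood absence epilepsy) in MEG/EEG sensor data who want a tested,
reproducible implementation of the classic correlation-network pipeline:
band decomposition, correlation matrices with significance thresholding,
graph-theoretic network summaries, spatial network-pattern calls and the
group statistics — and who want to know, via planted-ground-truth
experiments, what that pipeline can and cannot detect.

## The method

For each seizure three segments are analysed — ictal (3 s from onset),
termination (3 s before offset) and interictal (30 s, ≥ 10 s away) — in seven
bands: delta (1–4 Hz), theta (4–8), alpha (8–12), beta (12–30), gamma
(30–80), ripple (80–250), fast ripple (250–500).  Per segment and band:

* **FC matrix** — Pearson correlation for every channel pair,
  `R = C(X_a, X_b) / (S_a · S_b)`.
* **Thresholding** — an edge survives when `T = R·√(K−2)/√(1−R²)` exceeds the
  two-sided critical t at significance α (default 0.05), i.e.
  `|R| ≥ t_crit/√(K−2+t_crit²)`.  Positive edges are excitatory, negative
  inhibitory.
* **Graph metrics** — average strength S (mean |R| over edges), degree
  D = 2|E|/n, shortest path length L (hops, over connected pairs) and
  clustering coefficient C.
* **Pattern call** — frontal / posterior / anterior–posterior / distributed,
  by which edge class (both ends frontal; both posterior; one of each;
  other) holds ≥ 50% of the edges.
* **Statistics** — Fisher's exact test on pattern counts between periods,
  paired t-tests on S/D/L/C per band, partial correlations with clinical
  features (adjusted for age, sex, disease duration), Bonferroni + BH-FDR
  over the 7-band × 4-metric family.

The synthetic generator plants 1/f background, calibrated band-limited
coupling (shared-latent mixing with expected in-band correlation equal to the
requested rho) and 3 Hz spike-and-wave morphology, so recovery of known
structure is a testable property.  See `docs/methods.md` for assumptions,
parameter defaults and the effective-sample-count option for band-limited
thresholding.

## Worked example

```python
from megfc.synth import gamma_recovery_design, simulate_study
from megfc.pipeline import recovery_config, analyze_study

# a 33-seizure cohort (22 patients) with frontal gamma coupling during ictal
# windows and frontal-posterior gamma coupling during termination windows
dataset = simulate_study(gamma_recovery_design(seed=1))
result = analyze_study(dataset, recovery_config())

g = result.patterns.query("band == 'gamma'")
print(g.groupby("period")["label"].value_counts())
row = result.metric_tests.query("band == 'gamma' and metric == 'S'").iloc[0]
print(f"gamma S: ictal {row.mean_ictal:.3f} -> termination "
      f"{row.mean_termination:.3f}, t = {row.statistic:.1f}, "
      f"p_bonf = {row.p_bonf:.2e}")
```

prints

```
period       label
ictal        frontal               33
termination  anterior_posterior    33
Name: count, dtype: int64
gamma S: ictal 0.262 -> termination 0.330, t = 15.3, p_bonf = 7.93e-15
```

i.e. every ictal gamma network is called frontal, every termination network
anterior–posterior, and the planted strength increase at 30–80 Hz is detected
after correction.

The same pipeline runs from the shell on datasets in the documented
HDF5/TSV formats:

```sh
megfc simulate --design demo --out data/ --seed 1
megfc validate --data data/
megfc run-all --data data/ --out results/
```

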