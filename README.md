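# mnemonet

Continuous-report memory modelling and hippocampal–cortical network
connectivity analysis, with a fully synthetic test bench.

`mnemonet` is aimed at cognitive-neuroimaging researchers studying how the
posterior-medial (PM) and anterior-temporal (AT) cortical systems and the
hippocampus support episodic recollection. It implements, as a tested and
reusable library:

- **Circular mixture modelling** of continuous-report memory errors. The
  wrapped error θ̂ − θ (response minus target, in (−180°, 180°]) is modelled
  as p(θ) = (1 − γ)·φ_k(θ) + γ/2π, a zero-mean von Mises component
  (concentration *k*, memory precision) plus a uniform guess component
  (weight γ, guess rate), fitted by multi-start maximum likelihood. The
  posterior probability that an error came from the memory component yields
  a principled correct/incorrect threshold (the |error| where the posterior
  crosses 0.5).
- **Trial scoring**: success flags per feature, precision (180 − |error| on
  correct trials), a composite 0–3 memory-quality score (emotion 0/0.5/1
  plus threshold-scaled color and scene precision), and chance-level
  subject exclusion (mean |error| ≥ 75°).
- **Feature-binding dependency**: corrected dependency
  (P_AB + P_A′B′) − (P_A·P_B + P_A′·P_B′) per feature pair, plus
  Fisher-z precision–success and precision–precision correlations and group
  t tests.
- **Background connectivity**: per-run denoising (demean, detrend, 1/128 Hz
  high-pass, nuisance + task/memory regression), HRF-weighted Pearson
  correlation matrices per task condition, r ≥ 0.25 thresholding, Louvain
  modularity Q, within/between-network density, and encoding-vs-retrieval
  paired tests with 2×2 repeated-measures F contrasts.
- **Memory-modulated gPPI**: seed→target effective connectivity modulated
  by trial memory quality or feature precision (interaction of the observed
  seed series with the HRF-convolved modulator), network-level aggregation
  over the 3×3 directed PM/AT/HIPP cells, one-tailed group tests with
  Benjamini–Hochberg FDR, and the univariate parametric-activity GLM.
- **A synthetic-data generator** that emulates the study structure end to
  end — 28 subjects × 6 blocks × 24 trials with 45° within-block feature
  separation, mixture-distributed errors with a planted latent-state
  dependency, and multi-run BOLD-like ROI series (6 × 466 scans, TR 1.5 s)
  with network-structured covariance, retrieval-specific between-network
  coupling, and planted seed × modulator interactions — so every stage is
  testable against known ground truth.

## Worked example

Each script in `examples/` demonstrates one capability. Fitting the mixture
to simulated color-report errors (`python examples/01_mixture_model.py`):

```
true parameters:    k = 5.40, gamma = 0.33
fitted parameters:  k = 5.35, gamma = 0.33 (log-likelihood -4017.7, n = 3000)
success threshold:  +/-57.0 degrees
chance-level mean absolute error: 90 degrees
```

The fitted concentration and guess rate recover the generating values, and
the derived ±57° threshold marks where a response becomes more likely a
guess than a memory. Comparing background connectivity between tasks
(`python examples/03_background_connectivity.py`):

```
6 runs x 466 scans at TR 1.5s, 12 ROIs (5 PM, 5 AT, 2 HIPP)
  encoding : Q = 0.540  within-network density = 0.495  between-network density = 0.000
  remember : Q = 0.418  within-network density = 0.505  between-network density = 0.035
```

Retrieval lowers modularity and raises between-network density relative to
encoding — the planted retrieval-specific coupling makes the network less
compartmentalized, and the pipeline detects it.

The end-to-end pipeline is also exposed as a thin CLI:

```bash
mnemonet simulate --profile small --seed 7 -o out/   # trials + time series
mnemonet all --profile small --seed 7 -o out/        # full results bundle
mnemonet fit-behavior out/trials.csv --feature color
```

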