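# switchtissue

Quantitative analysis of pulsatile reporter-gene transcription in living
tissue.  Long-term fluorescence imaging of single cells (days of data at
15-minute sampling) shows genes switching between transcriptional states
at irregular times and heterogeneous levels; the scientific questions are
*when* each cell switches, *between which rates*, and *whether
neighbouring cells coordinate* their switching.  `switchtissue` is a
library for researchers analysing such data — and for method developers
who need a fully controlled synthetic test bed — covering the complete
chain from raw traces to tissue-level statistics.

## The model

Reporter fluorescence is linked to transcription through the stochastic
reaction network

```
∅ --β(t)--> mRNA,   mRNA --δm--> ∅,   mRNA --α--> mRNA + P,   P --δp--> ∅
Y(t) = κ·P(t) + ε,  ε ~ N(0, σ²)
```

with a piecewise-constant transcription rate β(t) = βᵢ on [sᵢ₋₁, sᵢ):
K unknown switch times and K+1 unknown rates.  Because the network is
linear, the mean and covariance obey closed ODEs (the linear noise
approximation is exact here), so the likelihood of a trace is evaluated
by a Kalman filter with closed-form propagators.  A reversible-jump MCMC
sampler explores profiles of varying K under informative degradation
priors; post-processing condenses the posterior into a small set of
mutually exclusive candidate profiles with probability weights (Gaussian
mixture on the switch-time marginal + sub-model enumeration).  Spatial
analyses — Ripley's K, distance-binned trace correlation against
trace-permutation nulls, transitive connectivity networks, and
switch-direction synchrony — quantify coordination between cells.  A
synthetic-tissue generator (telegraph-with-priming transcription, exact
Gillespie simulation, detector model, spatially coupled pulses) provides
ground truth for every stage.

See `docs/methods.md` for the full model description, defaults and design
choices.

## Worked example

Infer one cell's transcription profile from a noisy synthetic trace
(`examples/infer_switches.py`; ground truth: one switch from 5 to
25 a.u./h at t = 20 h):

```
$ python examples/infer_switches.py
posterior over switch count K: {1: 1551, 2: 221, 3: 24, 4: 4}
  profile K=1 switches=[19.94] rates=[ 6. 31.] weight=0.48
  profile K=1 switches=[19.84] rates=[ 5.5 29.1] weight=0.40
  profile K=2 switches=[ 9.97 19.94] rates=[ 5.8  6.6 34.3] weight=0.02
  profile K=2 switches=[17.19 19.84] rates=[ 5.7  4.4 27.4] weight=0.02
recursive residuals: KS vs N(0,1) p = 0.59, lag-1 acf = -0.040 (band +/-0.144)
```

The posterior puts most of its mass on single-switch profiles with the
switch within ~0.2 h of the truth; the recursive-residual diagnostics
(KS p-value well above 0.05, lag-1 autocorrelation inside the white-noise
band) confirm the fitted model explains the trace.

Detect the spatial coordination range on a simulated tissue
(`examples/spatial_coordination.py`; pulses propagate within 30 µm):

```
coupled: significant range endpoint = 30.0 um
  [  10,  15) um  n=63   median r=+0.327  p_perm=0.0005
  [  25,  30) um  n=156  median r=+0.376  p_perm=0.0005
  [  30,  35) um  n=149  median r=+0.145  p_perm=0.0455
  [  35,  40) um  n=183  median r=+0.127  p_perm=0.2630
uncoupled: significant range endpoint = 0.0 um
```

Cell pairs within the coupling radius are far more correlated than any
trace permutation allows (p < 0.001); beyond it the correlation drops to
noise, so the significant range recovers the generative 30 µm radius.
The uncoupled control shows no structure at any distance.

The other scripts in `examples/` each exercise one capability: tissue
simulation, trace preprocessing (detector fusion, background,
autocorrelation), switch synchrony, and the primed-shortening population
response.  The `switchtissue` command runs the whole pipeline
(`simulate → preprocess → infer → postprocess → spatial`) from a YAML
config:

```bash
switchtissue run --config cfg.yaml --seed 1 --out results/
```

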