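# Methods

This note documents the models, statistics and design choices behind
`switchtissue`, in the spirit of a package methods appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic-data experiments do and do not demonstrate.

## The reporter model

A destabilised fluorescent reporter under the control of a pulsatile gene
is modelled by the linear reaction network

    ∅ --β(t)--> mRNA        (transcription, piecewise constant)
    mRNA --δm--> ∅          (mRNA degradation)
    mRNA --α--> mRNA + P    (translation)
    P --δp--> ∅             (protein degradation)

observed through Y(t) = κ·P(t) + ε(t), ε ~ N(0, σ²).  The transcription
function β(t) = βᵢ on [sᵢ₋₁, sᵢ) has K switch times and K+1 interval
rates (we resolve the ambiguity of "K switches with K rates" in favour of
K+1 interval rates; a function with K jumps has K+1 levels).  Binary
on/off behaviour is the special case βᵢ ∈ {β_low, β_high}; nothing in the
inference restricts the levels, so a continuous range of transcription
rates is representable.

Default kinetics (`KineticParams`): δm = 0.7 h⁻¹, δp = 0.35 h⁻¹ (a ~2 h
protein half-life on the scale of destabilised GFP variants), α = 5 h⁻¹,
κ = 1, σ² = 25 a.u.².  These are package defaults, not measured values;
the degradation rates carry informative log-normal priors during
inference (location = log default, scale 0.2) because rate, translation
and scale parameters are not jointly identifiable from fluorescence
alone.  α and κ are fixed rather than sampled, so inferred rates are in
fluorescence-equivalent units — an honest, identifiable parameterisation.

## LNA likelihood

Because all propensities are linear, the "linear noise approximation"
moment equations for this network are exact in mean and covariance:

    dm/dt = A m + (β, 0)ᵀ,   A = [[−δm, 0], [α, −δp]]
    dV/dt = A V + V Aᵀ + Q(m),  Q = diag(β + δm·m₁, α·m₁ + δp·m₂)

A Kalman filter assimilates the observations; the marginal likelihood is
the product of one-step-ahead predictive densities.  Numerics: A is 2×2
lower triangular, so the exponential propagator and the input response
have closed forms; the process-noise integral over a step reduces to
three matrices multiplying (m₁, m₂, β) linearly, precomputed per step
length by Simpson quadrature (64 panels) on closed-form integrands.  The
per-step update is then a handful of scalar operations, and switch times
falling between observations are handled by exact sub-segment splits.
The initial state is the stationary distribution of the first segment
(tissue is assumed settled before imaging starts; overridable).  A
brute-force reference filter (`dense_kalman_loglik`, RK4 on the raw
moment ODEs at dt = 10⁻³–2·10⁻³ h) is kept in the package purely as a
numerical cross-check; the two agree to better than 10⁻⁴ in log
likelihood over random profiles.

Degenerate inputs: σ² = 0 with inconsistent data returns −∞ (not an
error); a filtered variance that turns negative beyond the relative
rounding budget raises (naming the timepoint), smaller negatives are
clipped to zero.  Inside the sampler such a failure — it happens when a
proposal conflicts with the data badly enough that the filtered mRNA
mean goes negative, so the state-dependent noise integral loses
positivity — is caught and treated as log-likelihood −∞, i.e. the
proposal is rejected rather than the chain aborted.

## Reversible-jump MCMC

The sampler explores (K, s, β, δm, δp, σ²) with move types: switch birth
(uniform position; the host interval's rate splits as β·e^{±u},
u ~ N(0, τ_b²), Jacobian |J| = 2β), death (the exact reverse, merged rate
√(β_l·β_r)), a reflected Gaussian random walk on one switch time, and
log-normal random walks on one rate, the degradation pair, and σ².  One
move is drawn per iteration with probabilities (0.15, 0.15, 0.2, 0.3,
0.1, 0.1).  Priors: truncated geometric on K (p = 0.5, K_max = 10 —
penalises complexity monotonically), ordered uniform switch times with a
minimum separation Δ_min = 0.5 h (two sampling intervals; switches below
grid resolution are meaningless), log-normal rates (location log 5,
scale 1.5), inverse-gamma σ² (shape 2, scale 25).  Defaults: 20 000
iterations, 5 000 burn-in, thinning 5.  Correctness checks: the
birth/death proposal log-ratios cancel exactly, and a likelihood-free run
reproduces the truncated-geometric K prior (χ² test on a heavily thinned
chain — the K random walk retains lag-100 autocorrelation ≈ 0.25, so the
χ² p-value is mildly anti-conservative at lighter thinning).

A hierarchical layer shares information on log δm, log δp across cells of
one dataset through a normal population model with a conjugate
normal-inverse-gamma hyperprior (`hierarchical_sweep` performs the Gibbs
update and re-centres per-cell priors); with a single cell it degenerates
to the fixed informative prior.

Model fit is checked by recursive residuals: standardised one-step-ahead
prediction errors under the point-estimate profile (modal K, conditional
posterior means).  For a well-specified model they are approximately iid
standard normal; a KS statistic against N(0,1) and the lag-1
autocorrelation with its ±1.96/√N band quantify departures.

## Posterior post-processing

The pooled switch-time draws are summarised by a Gaussian mixture
(1..8 components, BIC-selected — the component cap and criterion are
package choices).  Each draw maps to the subset of candidate components
its switches occupy (nearest component within ±3 SD, assignments strictly
increasing; otherwise the draw is unclassifiable and dropped, with an
error if more than half the draws drop).  Sub-models (subsets) become
mutually exclusive candidate profiles; their weights are sampling
frequencies and their rates conditional posterior means (means rather
than modes — a package choice, the alternative is not materially
different for unimodal conditionals).  Two candidate switches therefore
enumerate to at most four profiles: ∅, {s₁}, {s₂}, {s₁, s₂}.

Downstream weighted summaries: switch-count histograms (each profile
contributes its weight at its K), occupancy-weighted rate distributions
(each interval weighted by profile weight × interval duration; Gaussian
kernel, Silverman bandwidth on the weighted sample, with a 5%-of-scale
fallback for degenerate samples), state durations binned by rate deciles
or by a lower-75%/upper-25% split (window-truncated first/last intervals
are *minimum* durations: they are kept and flagged as censored rather
than dropped), a Low/Active classification (Low = flanked by two higher
rates; boundary intervals are Active; no-switch cells are excluded),
completely observed inter-switch times (profiles with ≥ 2 switches
only), and a bootstrap Mann–Whitney group comparison: per replicate one
duration is sampled per cell from its weighted distribution, and the
result is the histogram of replicate p-values with the fraction below the
0.5% line (5% overall with a tenfold Bonferroni correction); the
significance call is a majority of mass below the line.

## Spatial statistics

*Ripley's K*: translation edge correction in a rectangular window, where
the correction is closed-form and the estimator exactly unbiased under
CSR (the generator places cells in a known rectangle; for real data with
an irregular field a convex-hull window would need numerically computed
intersection areas — out of scope here).  The CSR envelope is the
pointwise min/max of 99 simulations by default, with a 2.5/97.5
percentile option.

*Correlation vs distance*: pair correlations of standardised traces
(Pearson's r; standardisation is the default because the raw mean
cross-product is scale-dependent — the literal statistic is kept as an
option), binned by inter-cell distance (half-open 5 µm bins from 5 µm;
closer pairs fall in the first bin).  Per bin: the median with a 90%
bootstrap band (99 resamples of the bin's pairs).  The null reference
permutes traces over cells with positions fixed; because relabelling
cells only re-indexes the correlation matrix, thousands of permutations
cost almost nothing.  Two significance measures are reported:

* `p_perm` — a one-sided permutation p-value of the observed **bin mean**
  against the permutation distribution of bin means.  This drives the
  significance call (α = 0.001) and the significant range.  The mean is
  the test statistic because pair correlations are bounded and
  light-tailed, where the mean dominates the median in power; the
  permutation test is exactly calibrated for any statistic.
* `p_ttest` — a paired t-test of the 99 observed bootstrap medians
  against the bootstrap medians of one permuted dataset, retained as a
  descriptive diagnostic.  It treats bootstrap-replicate noise as the
  sampling noise of the bin median and ignores the between-permutation
  component, so it is strongly anti-conservative; it must not be used as
  the significance call.

The significant range is the right edge of the *maximal* run of
consecutive significant bins (ties resolved toward low distance);
structurally empty leading bins — below the hard-core cell separation
there are no pairs by construction — do not break a run.  Note that
p < 0.001 requires more than 1000 permutations to be attainable
(defaults use 1999).

*Connectivity*: cells are discs of diameter D; pairs closer than D are
directly connected, connectivity is transitive (union-find components),
pairs in the same component at distance ≥ D are indirectly connected, the
rest unconnected — the three classes partition all pairs.  Per-class
correlation summaries are paired with a trace-permutation baseline, over
a sweep of D.

*Switch synchrony*: per cell pair, one profile is sampled per cell
(weight-proportional; for ground-truth profiles this is degenerate) and
every cross-cell switch pair is recorded with its |Δt|, direction match
(sign of the rate change at each switch) and distance class (within /
beyond 30 µm).  One-sided KS tests ask whether close same-direction (and
separately close opposite-direction) pairs switch within smaller
intervals than distant ones.  Resampling can be pooled over repeated
profile draws (`n_resample`) to reduce profile-sampling noise; note that
pooling inflates the nominal KS sample size, so pooled p-values are
indicative only — the single-draw mode is used for all calibrated
statements.

## Synthetic tissue generator

The generator is the package's stand-in for real imaging data and defines
the study conditions for every end-to-end experiment.

*State process*: each cell cycles off → primed → on → off with
exponential sojourns (defaults: 20 h, 8 h, 22 h).  The primed state
transcribes at β_low (default 0) — indistinguishable from off in rate,
distinguishable only in dynamics.  Each "on" sojourn draws its rate from
LogNormal(log 10, 0.5), so active transcription spans a continuous range
of levels.  With these defaults a cell shows ~2 intrinsic switches per
46 h window (up to ~4 including propagated events), matching pulsatile
reporter activity in adult tissue.  The primed mean may follow a
piecewise-constant schedule (applied at sojourn entry) to model a
population-level change in the refractory period.

*Spatial layout*: hard-core placement (minimum separation 10 µm — finite
cell size) of 300 cells in a 650 × 650 µm field, i.e. ~2–3 neighbours
within the 30 µm coupling radius.  The density was chosen by a design
analysis: under a fixed per-cell switch budget the shared-event fraction
of a direct pair scales like 2p/(1 + p·ν) (p = per-contact coupling
probability, ν = neighbours in range), so a sparse contact network with
strong per-contact coupling is the regime in which a coordination range
equal to the direct-contact scale is detectable at all; denser fields
dilute each cell's trace with many weakly shared events.

*Coupling*: an explicit statistical stand-in, not a mechanism.  Each
complete "on" pulse (up-switch plus closing down-switch, at least 4 h
wide) is copied, with probability 0.8 per neighbour within 30 µm, into
the neighbour's profile: both edges at the source times plus independent
N(0, 1 h) jitters, at the source's rate level, provided the copy fits
into one of the neighbour's existing intervals and recruits it upward.
Copies that do not fit contribute their up edge only (the target's own
next switch closes the excursion), and no copy may flip or erase the
direction of any of the target's switches.  Several simpler mechanisms
were implemented and rejected because they manufacture *synchronised
opposite-direction switch pairs* — a signature coordinated tissue data
explicitly lacks: single-switch insertion copies both edges of short
pulses (one cell's up lands next to the other's down at Δt ≈ pulse
width), clipping copies to the host interval plants down-edges against
the target's own up-switches, and state-dependent insertion feasibility
correlates source times with the target's phase.  The pulse-copy form
with a minimum source-pulse width avoids the sharp channels; the copied
down-edge offsets are distributed like the on-sojourn (Exp(22 h)), which
over a 46 h window is almost indistinguishable from the background
|Δt| distribution of unrelated switch pairs.  A residual, weak
opposite-direction structure remains — chance coincidences of
independent source pulses in one neighbourhood are amplified when both
are broadcast — and is invisible at the field sizes analysed in practice
(~150 cells) while becoming detectable when many hundreds of cells'
switch pairs are pooled.  This is a property of any broadcast-style local
coordination, not an implementation artefact.

*Reporter and detector*: exact Gillespie simulation of the network
(piecewise-constant β handled by re-drawing the waiting time at switch
boundaries, valid by memorylessness), integer counts sampled on the
imaging grid; per channel the measurement is clip(gain·κ·P + noise, 0,
ceiling).  A sensitive channel (high gain, low ceiling) plus an
insensitive channel (low gain, no ceiling) reproduces dual-detector
acquisition; background traces are pure measurement noise.

What the generator does **not** emulate: cell movement (centroids are
constant, so median positions are exact), photobleaching and focus drift,
slow field-wide trends (e.g. release from upstream inhibition — absent so
that coordination signals are not confounded), segmentation errors and
signal spill-over between neighbouring ROIs, mid-track cell loss, and any
mechanistic model of cell–cell communication.  Passing end-to-end tests
therefore shows that the *analysis* recovers the *generative*
coordination structure; it does not validate the coupling stand-in as a
model of tissue biology.

## Preprocessing

Dual-detector fusion regresses the sensitive channel on the insensitive
one over unsaturated timepoints (below the saturation ceiling; at least
5 required, positive slope required) and splices the regression-rescaled
insensitive channel in above a threshold (default 95% of the ceiling).
The regression direction and exclusion rule are package choices.
Background subtraction removes the per-timepoint mean of the background
traces and floors negatives at zero (logged).  The autocorrelation
diagnostic uses the biased (1/N) normalisation, under which the
±1.96/√N white-noise band is standard.  No detrending, bleaching
correction or smoothing is applied — the inference model consumes raw
fused traces.

## Problem sizes in the verification experiments

The acceptance experiments (tests and `scripts/acceptance.py`) use:
200 white-noise traces × 185 points; 10 random profiles for the
likelihood oracle; 200 Gillespie replicates for the stationary moments;
10 single-switch cells at 20 000 MCMC iterations plus one 150 000
iteration prior-only chain; 50 × 150-cell uncoupled tissues for
permutation-null calibration and 10 × 300-cell coupled tissues for
coordination-range recovery (1999 permutations each); one 150-cell
coupled plus one uncoupled tissue for synchrony (a single imaging field's
worth of cells — the scale at which the opposite-direction null holds,
see above); 20 × 200-point CSR patterns with 99-simulation envelopes; and
100 cells over 120 h for the primed-shortening response (priming-heavy
sojourn means 6/16/10 h, primed mean halved mid-course, plateaus compared
over ≥ 30 h windows).  These sizes give each stochastic check comfortable
statistical resolution while keeping the full suite inside a coffee
break.

## Known limitations

* The LNA-Gaussian likelihood is exact in its first two moments but still
  approximates Poissonian counts by a Gaussian; at very low copy numbers
  (β ≲ 1 h⁻¹) the predictive tails are mildly wrong.
* α and κ are fixed; absolute transcription rates are reported in
  fluorescence-equivalent units and are only as meaningful as the
  assumed scale.
* Sub-model enumeration conditions on the Gaussian-mixture summary of
  the switch marginal; heavily overlapping candidate switches can make
  draws unclassifiable (reported, and an error above 50%).
* The K random walk of the sampler mixes slowly on flat likelihoods;
  prior-reproduction checks need heavy thinning.
* The coupling stand-in reproduces the statistical signatures of local
  coordination, not its biology; parameters (radius, probability,
  jitter) are free knobs, and inference about real mechanisms must come
  from real perturbation data.
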