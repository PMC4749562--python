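"""Reversible-jump MCMC over piecewise-constant transcription profiles.

The sampler explores (K, s, beta, delta_m, delta_p, sigma2): the number K
and times s of transcription switches, the K+1 interval rates, the two
degradation rates (under informative log-normal priors, since rate,
translation and scale parameters are not jointly identifiable from
fluorescence alone) and the measurement noise variance.  Translation rate
alpha and fluorescence scale kappa are fixed, so rates are reported in
fluorescence-equivalent units.

Move types: switch birth (uniform position, log-normal split of the host
interval's rate), death (the exact reverse), Gaussian random-walk move of a
single switch time reflected at its neighbours, log-normal random walks on
one rate, on the degradation pair and on sigma2.  Birth/death acceptance
ratios carry the reversible-jump Jacobian |J| = 2*beta of the rate split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lna import LNAPropagator, lna_loglik
from .types import KineticParams, TranscriptionProfile

log = logging.getLogger(__name__)

_MOVES = ("birth", "death", "move", "rate", "degradation", "noise")


def _norm_logpdf(x: float, sd: float) -> float:
    return -0.5 * math.log(2.0 * math.pi) - math.log(sd) - 0.5 * (x / sd) ** 2


@dataclass
class PriorSpec:
    """Priors for the switch model.

    The degradation priors are informative log-normals (centred on
    independent estimates for a destabilised reporter); K has a truncated
    geometric prior penalising extra switches; switch times are uniform over
    the window subject to a minimum separation ``delta_min``; rates are
    log-normal; sigma2 is inverse-gamma.  alpha and kappa are fixed.
    """

    dm_log_mean: float = float(np.log(0.7))
    dm_log_sd: float = 0.2
    dp_log_mean: float = float(np.log(0.35))
    dp_log_sd: float = 0.2
    k_geom_p: float = 0.5
    k_max: int = 10
    beta_log_mean: float = float(np.log(5.0))
    beta_log_sd: float = 1.5
    delta_min: float = 0.5          # hours; default = 2 sampling intervals
    sigma2_shape: float = 2.0
    sigma2_scale: float = 25.0
    alpha: float = 5.0              # fixed
    kappa: float = 1.0              # fixed

    def __post_init__(self) -> None:
        if self.delta_min <= 0 or self.k_max < 0:
            raise ValueError("delta_min must be > 0 and k_max >= 0")
        if not 0 < self.k_geom_p < 1:
            raise ValueError("k_geom_p must lie in (0, 1)")


@dataclass
class HierarchySpec:
    """Population-level normal model for log degradation rates.

    log delta ~ N(mu, s^2) across cells, with a conjugate
    normal-inverse-gamma hyperprior (mu | s^2 ~ N(m0, s^2/k0),
    s^2 ~ InvGamma(a0, b0)).
    """

    dm_m0: float = float(np.log(0.7))
    dp_m0: float = float(np.log(0.35))
    k0: float = 1.0
    a0: float = 2.0
    b0: float = 0.08     # scale floor ~ sqrt(b0/a0) ~ 0.2 on the log scale

    def __post_init__(self) -> None:
        if min(self.k0, self.a0, self.b0) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class MCMCConfig:
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    tau_birth: float = 0.5     # SD of the log-normal rate split at birth
    tau_move: float = 1.0      # SD (h) of the switch-time random walk
    tau_rate: float = 0.4      # SD of the log-rate random walk
    tau_deg: float = 0.08      # SD of the log-degradation random walk
    tau_noise: float = 0.3     # SD of the log-sigma2 random walk
    move_probs: tuple[float, ...] = (0.15, 0.15, 0.2, 0.3, 0.1, 0.1)

    def __post_init__(self) -> None:
        if (self.n_iter - self.burn_in) // self.thin < 1:
            raise ValueError("chain configuration retains zero samples")
        if abs(sum(self.move_probs) - 1.0) > 1e-9 or len(self.move_probs) != 6:
            raise ValueError("move_probs must be 6 probabilities summing to 1")


@dataclass
class PosteriorSamples:
    """Retained RJMCMC draws for one cell plus the acceptance ledger."""

    k: np.ndarray                       # (R,)
    switch_times: list[np.ndarray]      # R arrays of length k[r]
    rates: list[np.ndarray]             # R arrays of length k[r] + 1
    delta_m: np.ndarray
    delta_p: np.ndarray
    sigma2: np.ndarray
    loglik: np.ndarray
    ledger: dict[str, tuple[int, int]]  # move -> (proposed, accepted)
    window: tuple[float, float]
    seed: int | None = None
    n_iter: int = 0
    burn_in: int = 0
    thin: int = 1

    def __len__(self) -> int:
        return len(self.k)

    def modal_k(self) -> int:
        vals, counts = np.unique(self.k, return_counts=True)
        return int(vals[np.argmax(counts)])

    def pooled_switch_times(self) -> np.ndarray:
        """All switch-time draws pooled over retained iterations."""
        if not self.switch_times:
            return np.empty(0)
        return np.concatenate([s for s in self.switch_times if len(s)] or [np.empty(0)])

    def mean_profile(self) -> TranscriptionProfile:
        """Point-estimate profile: modal K, conditional mean times and rates."""
        km = self.modal_k()
        idx = [i for i in range(len(self)) if self.k[i] == km]
        sw = (np.mean([self.switch_times[i] for i in idx], axis=0)
              if km > 0 else np.empty(0))
        rates = np.mean([self.rates[i] for i in idx], axis=0)
        return TranscriptionProfile(np.atleast_1d(np.asarray(sw, float)),
                                    np.asarray(rates, float))


def _log_prior_s(k: int, window: tuple[float, float], delta_min: float) -> float:
    """Log density of the ordered, separation-constrained uniform prior."""
    if k == 0:
        return 0.0
    t_eff = (window[1] - window[0]) - (k + 1) * delta_min
    if t_eff <= 0:
        return -math.inf
    return math.lgamma(k + 1) - k * math.log(t_eff)


class _Chain:
    """Mutable chain state with cached likelihood."""

    def __init__(self, times, y, priors: PriorSpec, rng, use_likelihood=True):
        self.times = np.asarray(times, float)
        self.y = np.asarray(y, float)
        self.window = (float(self.times[0]), float(self.times[-1]))
        self.priors = priors
        self.rng = rng
        self.use_likelihood = use_likelihood
        self.dm = math.exp(priors.dm_log_mean)
        self.dp = math.exp(priors.dp_log_mean)
        self.s2 = priors.sigma2_scale / max(priors.sigma2_shape - 1.0, 0.5)
        beta0 = max(float(np.mean(self.y)), 1e-3) * self.dm * self.dp / (
            priors.alpha * priors.kappa
        )
        self.sw = np.empty(0)
        self.rates = np.array([beta0])
        self._props: dict[tuple[float, float], LNAPropagator] = {}
        self.ll = self._loglik(self.sw, self.rates, self.dm, self.dp, self.s2)

    def _kp(self, dm, dp, s2) -> KineticParams:
        return KineticParams(delta_m=dm, delta_p=dp, alpha=self.priors.alpha,
                             kappa=self.priors.kappa, sigma2=s2)

    def _loglik(self, sw, rates, dm, dp, s2) -> float:
        if not self.use_likelihood:
            return 0.0
        key = (round(dm, 12), round(dp, 12))
        prop = self._props.get(key)
        if prop is None:
            if len(self._props) > 64:
                self._props.clear()
            prop = LNAPropagator(self._kp(dm, dp, s2))
            self._props[key] = prop
        profile = TranscriptionProfile.__new__(TranscriptionProfile)
        profile.switch_times = sw
        profile.rates = rates
        profile.weight = 1.0
        try:
            return lna_loglik(self.times, self.y, profile, self._kp(dm, dp, s2), prop=prop)
        except FloatingPointError:
            # a proposal so inconsistent with the data that the filtered
            # mean goes negative and the noise integral loses positivity:
            # treat as impossible rather than abort the chain
            return -math.inf

    # prior pieces -------------------------------------------------------
    def _lp_k(self, k: int) -> float:
        if k > self.priors.k_max:
            return -math.inf
        return k * math.log1p(-self.priors.k_geom_p)

    def _lp_beta(self, rates) -> float:
        p = self.priors
        if np.any(rates <= 0):
            return -math.inf
        lx = np.log(rates)
        return float(np.sum(-lx - 0.5 * ((lx - p.beta_log_mean) / p.beta_log_sd) ** 2
                            - math.log(p.beta_log_sd) - 0.5 * math.log(2 * math.pi)))

    def _lp_deg(self, dm, dp) -> float:
        p = self.priors
        out = 0.0
        for v, mu, sd in ((dm, p.dm_log_mean, p.dm_log_sd), (dp, p.dp_log_mean, p.dp_log_sd)):
            lv = math.log(v)
            out += -lv - 0.5 * ((lv - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
        return out

    def _lp_s2(self, s2) -> float:
        # inverse-gamma log density (closed form, avoids scipy call overhead)
        a, b = self.priors.sigma2_shape, self.priors.sigma2_scale
        return a * math.log(b) - math.lgamma(a) - (a + 1.0) * math.log(s2) - b / s2

    # separation helpers -------------------------------------------------
    def _separated(self, sw) -> bool:
        t0, t1 = self.window
        d = self.priors.delta_min
        if len(sw) == 0:
            return True
        if sw[0] < t0 + d or sw[-1] > t1 - d:
            return False
        return bool(np.all(np.diff(sw) >= d))


def rjmcmc_sample(
    times: np.ndarray,
    y: np.ndarray,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    rng: np.random.Generator | int | None = None,
    use_likelihood: bool = True,
    seed_label: int | None = None,
) -> PosteriorSamples:
    """Run the reversible-jump sampler on one fluorescence trace.

    With ``use_likelihood=False`` the chain targets the prior alone, which
    is the standard correctness check (the retained K distribution must then
    reproduce the truncated geometric prior).
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    if not isinstance(rng, np.random.Generator):
        seed_label = rng if seed_label is None else seed_label
        rng = np.random.default_rng(rng)
    ch = _Chain(times, y, priors, rng, use_likelihood)
    t0, t1 = ch.window
    T = t1 - t0
    dmin = priors.delta_min
    ledger = {m: [0, 0] for m in _MOVES}
    out_k, out_sw, out_rates, out_dm, out_dp, out_s2, out_ll = [], [], [], [], [], [], []
    move_idx = rng.choice(6, size=mcmc.n_iter, p=mcmc.move_probs)
    log_unif = np.log(rng.uniform(size=mcmc.n_iter))
    for it in range(mcmc.n_iter):
        move = _MOVES[move_idx[it]]
        ledger[move][0] += 1
        k = len(ch.sw)
        accept = False
        if move == "birth":
            if k < priors.k_max:
                s_new = rng.uniform(t0, t1)
                sw_new = np.sort(np.append(ch.sw, s_new))
                if ch._separated(sw_new):
                    j = int(np.searchsorted(ch.sw, s_new))
                    u = rng.normal(0.0, mcmc.tau_birth)
                    bj = ch.rates[j]
                    bl, br = bj * math.exp(u), bj * math.exp(-u)
                    rates_new = np.concatenate([ch.rates[:j], [bl, br], ch.rates[j + 1:]])
                    ll_new = ch._loglik(sw_new, rates_new, ch.dm, ch.dp, ch.s2)
                    la = (ll_new - ch.ll
                          + ch._lp_k(k + 1) - ch._lp_k(k)
                          + _log_prior_s(k + 1, ch.window, dmin) - _log_prior_s(k, ch.window, dmin)
                          + ch._lp_beta(rates_new) - ch._lp_beta(ch.rates)
                          # proposal: death picks 1 of k+1; birth density (1/T) * phi(u)
                          - math.log(k + 1) + math.log(T)
                          - _norm_logpdf(u, mcmc.tau_birth)
                          + math.log(2.0 * bj))
                    if la > log_unif[it]:
                        ch.sw, ch.rates, ch.ll = sw_new, rates_new, ll_new
                        accept = True
        elif move == "death":
            if k > 0:
                i = int(rng.integers(k))
                bl, br = ch.rates[i], ch.rates[i + 1]
                bm = math.sqrt(bl * br)
                u_rev = 0.5 * math.log(bl / br)
                sw_new = np.delete(ch.sw, i)
                rates_new = np.concatenate([ch.rates[:i], [bm], ch.rates[i + 2:]])
                if np.all(np.diff(rates_new) != 0):
                    ll_new = ch._loglik(sw_new, rates_new, ch.dm, ch.dp, ch.s2)
                    la = (ll_new - ch.ll
                          + ch._lp_k(k - 1) - ch._lp_k(k)
                          + _log_prior_s(k - 1, ch.window, dmin) - _log_prior_s(k, ch.window, dmin)
                          + ch._lp_beta(rates_new) - ch._lp_beta(ch.rates)
                          + math.log(k) - math.log(T)
                          + _norm_logpdf(u_rev, mcmc.tau_birth)
                          - math.log(2.0 * bm))
                    if la > log_unif[it]:
                        ch.sw, ch.rates, ch.ll = sw_new, rates_new, ll_new
                        accept = True
        elif move == "move":
            if k > 0:
                i = int(rng.integers(k))
                lo = (ch.sw[i - 1] + dmin) if i > 0 else (t0 + dmin)
                hi = (ch.sw[i + 1] - dmin) if i < k - 1 else (t1 - dmin)
                s_prop = ch.sw[i] + rng.normal(0.0, mcmc.tau_move)
                # reflect into (lo, hi); symmetric proposal
                width = hi - lo
                if width > 0:
                    z = (s_prop - lo) % (2 * width)
                    s_prop = lo + (z if z <= width else 2 * width - z)
                    sw_new = ch.sw.copy()
                    sw_new[i] = s_prop
                    ll_new = ch._loglik(sw_new, ch.rates, ch.dm, ch.dp, ch.s2)
                    if ll_new - ch.ll > log_unif[it]:
                        ch.sw, ch.ll = sw_new, ll_new
                        accept = True
        elif move == "rate":
            i = int(rng.integers(k + 1))
            b_new = ch.rates[i] * math.exp(rng.normal(0.0, mcmc.tau_rate))
            rates_new = ch.rates.copy()
            rates_new[i] = b_new
            if np.all(np.diff(rates_new) != 0):
                ll_new = ch._loglik(ch.sw, rates_new, ch.dm, ch.dp, ch.s2)
                la = (ll_new - ch.ll
                      + ch._lp_beta(rates_new) - ch._lp_beta(ch.rates)
                      + math.log(b_new) - math.log(ch.rates[i]))
                if la > log_unif[it]:
                    ch.rates, ch.ll = rates_new, ll_new
                    accept = True
        elif move == "degradation":
            dm_new = ch.dm * math.exp(rng.normal(0.0, mcmc.tau_deg))
            dp_new = ch.dp * math.exp(rng.normal(0.0, mcmc.tau_deg))
            ll_new = ch._loglik(ch.sw, ch.rates, dm_new, dp_new, ch.s2)
            la = (ll_new - ch.ll
                  + ch._lp_deg(dm_new, dp_new) - ch._lp_deg(ch.dm, ch.dp)
                  + math.log(dm_new / ch.dm) + math.log(dp_new / ch.dp))
            if la > log_unif[it]:
                ch.dm, ch.dp, ch.ll = dm_new, dp_new, ll_new
                accept = True
        else:  # noise
            s2_new = ch.s2 * math.exp(rng.normal(0.0, mcmc.tau_noise))
            ll_new = ch._loglik(ch.sw, ch.rates, ch.dm, ch.dp, s2_new)
            la = (ll_new - ch.ll
                  + ch._lp_s2(s2_new) - ch._lp_s2(ch.s2)
                  + math.log(s2_new / ch.s2))
            if la > log_unif[it]:
                ch.s2, ch.ll = s2_new, ll_new
                accept = True
        if accept:
            ledger[move][1] += 1
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            out_k.append(len(ch.sw))
            out_sw.append(ch.sw.copy())
            out_rates.append(ch.rates.copy())
            out_dm.append(ch.dm)
            out_dp.append(ch.dp)
            out_s2.append(ch.s2)
            out_ll.append(ch.ll)
    return PosteriorSamples(
        k=np.array(out_k),
        switch_times=out_sw,
        rates=out_rates,
        delta_m=np.array(out_dm),
        delta_p=np.array(out_dp),
        sigma2=np.array(out_s2),
        loglik=np.array(out_ll),
        ledger={m: (c[0], c[1]) for m, c in ledger.items()},
        window=ch.window,
        seed=seed_label if isinstance(seed_label, int) else None,
        n_iter=mcmc.n_iter,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
    )


def birth_death_logratio(
    rates: np.ndarray, j: int, u: float, tau_birth: float, window: tuple[float, float],
    k: int, T_eff_terms=None,
) -> tuple[float, float]:
    """Forward birth and reverse death proposal log-ratio pieces.

    Exposes the reversible-jump bookkeeping for direct testing: for any
    state, the birth log proposal ratio and the death log proposal ratio of
    the exact reverse move must sum to zero.
    """
    T = window[1] - window[0]
    bj = float(rates[j])
    birth = (-math.log(k + 1) + math.log(T)
             - _norm_logpdf(u, tau_birth) + math.log(2.0 * bj))
    bl, br = bj * math.exp(u), bj * math.exp(-u)
    bm = math.sqrt(bl * br)
    u_rev = 0.5 * math.log(bl / br)
    death = (math.log(k + 1) - math.log(T)
             + _norm_logpdf(u_rev, tau_birth) - math.log(2.0 * bm))
    return birth, death


def hierarchical_sweep(
    chains: list[PosteriorSamples],
    h: HierarchySpec | None = None,
    rng: np.random.Generator | int | None = None,
    priors: PriorSpec | None = None,
) -> tuple[dict, list[PriorSpec]]:
    """One Gibbs update of the population model for log degradation rates.

    Takes the current per-cell chains (their latest draws of delta_m and
    delta_p), samples the population location and scale from the conjugate
    normal-inverse-gamma posterior, and returns re-centred per-cell priors.
    With a single cell the update degenerates to the fixed informative prior
    (with a warning).
    """
    h = h or HierarchySpec()
    priors = priors or PriorSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if len(chains) < 2:
        log.warning("hierarchical sweep with < 2 cells: keeping fixed informative priors")
        pop = {
            "dm": (priors.dm_log_mean, priors.dm_log_sd),
            "dp": (priors.dp_log_mean, priors.dp_log_sd),
        }
        return pop, [priors for _ in chains]
    pop = {}
    import dataclasses as _dc

    new_fields: dict[str, float] = {}
    for name, m0 in (("dm", h.dm_m0), ("dp", h.dp_m0)):
        x = np.log([getattr(c, f"delta_{name[1]}")[-1] for c in chains])
        n = len(x)
        xbar = float(np.mean(x))
        kn = h.k0 + n
        mn = (h.k0 * m0 + n * xbar) / kn
        an = h.a0 + n / 2.0
        bn = h.b0 + 0.5 * float(np.sum((x - xbar) ** 2)) + (h.k0 * n * (xbar - m0) ** 2) / (2 * kn)
        s2 = float(stats.invgamma.rvs(an, scale=bn, random_state=rng))
        mu = float(rng.normal(mn, math.sqrt(s2 / kn)))
        pop[name] = (mu, math.sqrt(s2))
        new_fields[f"{name}_log_mean"] = mu
        new_fields[f"{name}_log_sd"] = math.sqrt(s2)
    cell_priors = [_dc.replace(priors, **new_fields) for _ in chains]
    return pop, cell_priors


@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    ks_stat: float
    ks_pvalue: float
    lag1_acf: float
    band: float
    profile: TranscriptionProfile


def recursive_residuals(
    times: np.ndarray,
    y: np.ndarray,
    samples: PosteriorSamples,
    kp_template: KineticParams | None = None,
) -> ResidualDiagnostics:
    """Standardised one-step-ahead prediction residuals as a model-fit check.

    Residuals are computed under the point-estimate profile (modal K,
    conditional posterior means) with the posterior-mean kinetic parameters.
    For a well-specified model they are approximately iid standard normal;
    the KS statistic against N(0,1) and the lag-1 autocorrelation with its
    white-noise band quantify departures.
    """
    if len(samples) == 0:
        raise ValueError("empty posterior samples")
    profile = samples.mean_profile()
    base = kp_template or KineticParams()
    kp = KineticParams(
        delta_m=float(np.mean(samples.delta_m)),
        delta_p=float(np.mean(samples.delta_p)),
        alpha=base.alpha,
        kappa=base.kappa,
        sigma2=float(np.mean(samples.sigma2)),
    )
    _, pred_mean, pred_var = lna_loglik(times, y, profile, kp, return_predictions=True)
    resid = (np.asarray(y, float) - pred_mean) / np.sqrt(pred_var)
    ks = stats.kstest(resid, "norm")
    n = len(resid)
    r = resid - resid.mean()
    lag1 = float(np.sum(r[1:] * r[:-1]) / np.sum(r * r))
    return ResidualDiagnostics(
        residuals=resid,
        ks_stat=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        lag1_acf=lag1,
        band=1.96 / math.sqrt(n),
        profile=profile,
    )
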