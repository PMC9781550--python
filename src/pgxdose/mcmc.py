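"""Ensemble-MCMC driver and posterior summaries.

All models in this package expose a vectorized log-posterior over an
unconstrained parameter vector (scale parameters are sampled on the log
scale with the appropriate Jacobian terms).  Sampling uses the emcee
affine-invariant ensemble sampler; convergence is monitored with split-Rhat
and bulk effective sample size computed across walkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

_LOG_2_OVER_PI = np.log(2.0 / np.pi)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# log-density helpers on the unconstrained (log) scale, Jacobians included
# ---------------------------------------------------------------------------

def log_half_cauchy(log_x: np.ndarray, scale: float) -> np.ndarray:
    """log p(log x) for x ~ half-Cauchy(0, scale), sampled as log x."""
    x = np.exp(log_x)
    return _LOG_2_OVER_PI - np.log(scale) - np.log1p((x / scale) ** 2) + log_x


def log_half_student_t(log_x: np.ndarray, scale: float, df: int) -> np.ndarray:
    """log p(log x) for x ~ half-Student-t(0, scale, df), sampled as log x."""
    from scipy.special import gammaln

    x = np.exp(log_x)
    const = (
        gammaln((df + 1) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        + np.log(2.0)
    )
    return const - (df + 1) / 2.0 * np.log1p((x / scale) ** 2 / df) + log_x


def log_lognormal_scale(log_x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """log p(log x) for x ~ log-normal(mu, sd), sampled as log x.

    The -log x of the lognormal density cancels against the +log x Jacobian.
    """
    return -0.5 * ((log_x - mu) / sd) ** 2 - np.log(sd) - _HALF_LOG_2PI


def log_half_normal(log_x: np.ndarray, sd: float) -> np.ndarray:
    """log p(log x) for x ~ half-normal(0, sd), sampled as log x."""
    x = np.exp(log_x)
    return 0.5 * np.log(2.0 / np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2 + log_x


# ---------------------------------------------------------------------------
# sampler configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    """Ensemble-sampler settings.

    n_chains independent walker ensembles are run (Stan-style chains for the
    split-Rhat diagnostic); within each, n_walkers default to
    max(16, 2 x ndim + 4).  n_steps counts post-burn ensemble moves, of
    which every thin-th is retained.
    """

    n_steps: int = 1500
    n_burn: int = 1500
    n_chains: int = 4
    n_walkers: int | None = None
    thin: int = 6
    seed: int = 0
    rhat_threshold: float = 1.01
    min_acceptance: float = 0.05

    def walkers(self, ndim: int) -> int:
        return self.n_walkers or max(16, 2 * ndim + 4)

    def with_seed(self, seed: int) -> "McmcConfig":
        return McmcConfig(
            n_steps=self.n_steps,
            n_burn=self.n_burn,
            n_chains=self.n_chains,
            n_walkers=self.n_walkers,
            thin=self.thin,
            seed=int(seed),
            rhat_threshold=self.rhat_threshold,
            min_acceptance=self.min_acceptance,
        )


#: Faster settings for simulation studies at reduced problem sizes.
FAST_MCMC = McmcConfig(n_steps=600, n_burn=600, thin=4)


@dataclass
class EnsembleResult:
    """Flattened posterior draws plus convergence diagnostics.

    ``chain`` holds the retained draws as (T, n_chains, ndim) where each
    independent ensemble's walkers are flattened step-major into one chain,
    so splitting a chain in half separates early from late steps.
    """

    draws: np.ndarray            # (T * n_chains, ndim)
    chain: np.ndarray            # (T, n_chains, ndim)
    acceptance: float
    rhat: np.ndarray             # per-parameter split-Rhat across ensembles
    ess: np.ndarray              # per-parameter bulk ESS
    reliable: bool = True
    messages: list[str] = field(default_factory=list)

    def flag(self, msg: str) -> None:
        self.reliable = False
        self.messages.append(msg)


def rhat_of_chains(chain: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter of a (draws, walkers, ndim) chain array.

    Walkers are treated as chains and each is split in half, so slow trends
    within the run inflate the statistic as they should.
    """
    T, C, P = chain.shape
    if P == 0:
        return np.array([])
    half = T // 2
    split = np.concatenate([chain[:half], chain[half : 2 * half]], axis=1)  # (half, 2C, P)
    mean_c = split.mean(axis=0)
    var_c = split.var(axis=0, ddof=1)
    W = var_c.mean(axis=0)
    B = half * mean_c.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_hat / W)
    return np.where(W > 0, out, 1.0)


def ess_of_chains(chain: np.ndarray) -> np.ndarray:
    """Effective sample size per parameter via FFT autocorrelation
    (Geyer initial-monotone truncation, averaged over walkers)."""
    T, C, P = chain.shape
    if P == 0:
        return np.array([])
    x = chain - chain.mean(axis=0, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[:T].real / T
    denom = acov[0].mean(axis=0)  # (P,)
    rho = acov.mean(axis=1) / np.where(denom > 0, denom, 1.0)  # (T, P)
    ess = np.empty(P)
    for p in range(P):
        s, t = 0.0, 1
        while t + 1 < T:
            pair = rho[t, p] + rho[t + 1, p]
            if pair < 0:
                break
            s += pair
            t += 2
        ess[p] = T * C / (1.0 + 2.0 * s)
    return np.minimum(ess, T * C)


def run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    config: McmcConfig,
) -> EnsembleResult:
    """Sample a vectorized log-posterior.

    ``log_prob`` maps a (n_walkers, ndim) array to (n_walkers,) log densities;
    ``init`` is a single unconstrained center point around which walkers are
    dispersed.  Runs config.n_chains independent ensembles with
    differential-evolution moves (better suited to the heavy-tailed scale
    posteriors than the stretch move) and pools their thinned post-burn
    draws.
    """
    import emcee

    ndim = len(init)
    nw = config.walkers(ndim)
    seeds = derive_seeds(config.seed, config.n_chains)
    per_chain = []
    acc = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        # overdispersed chain centers so stuck chains disagree and split-Rhat
        # can flag an under-burned run instead of silently passing it
        center = init + 0.75 * rng.standard_normal(ndim)
        p0 = center[None, :] + 0.1 * rng.standard_normal((nw, ndim))
        lp0 = log_prob(p0)
        bad = ~np.isfinite(lp0)
        tries = 0
        while bad.any() and tries < 50:
            p0[bad] = init[None, :] + 0.01 * rng.standard_normal((int(bad.sum()), ndim))
            lp0 = log_prob(p0)
            bad = ~np.isfinite(lp0)
            tries += 1
        if bad.any():
            raise RuntimeError("could not initialize walkers at finite log-density")

        sampler = emcee.EnsembleSampler(
            nw, ndim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(seed).get_state()
        state = sampler.run_mcmc(p0, config.n_burn, progress=False)
        sampler.reset()
        n_saved = max(config.n_steps // config.thin, 2)
        sampler.run_mcmc(state, n_saved, thin_by=config.thin, progress=False)
        per_chain.append(sampler.get_chain())                     # (T, nw, ndim)
        acc.append(float(np.mean(sampler.acceptance_fraction)))

    # one pseudo-chain per independent ensemble (walkers flattened step-major)
    chain = np.stack([c.reshape(-1, ndim) for c in per_chain], axis=1)
    draws = chain.reshape(-1, ndim)
    acceptance = float(np.mean(acc))
    rhat = rhat_of_chains(chain)
    # autocorrelation is a per-walker notion: stack walkers for the ESS
    ess = ess_of_chains(np.concatenate(per_chain, axis=1))

    result = EnsembleResult(draws=draws, chain=chain, acceptance=acceptance, rhat=rhat, ess=ess)
    if acceptance < config.min_acceptance:
        result.flag(f"low walker acceptance fraction {acceptance:.3f}")
    return result


def summarize(draws: np.ndarray, level: float = 0.90) -> dict[str, np.ndarray]:
    """Median and central interval of each column of a draw matrix."""
    a = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(draws, [a, 0.5, 1.0 - a], axis=0)
    return {"median": med, "lower": lo, "upper": hi}


def derive_seeds(seed: int, k: int) -> list[int]:
    """Derive k independent per-fit seeds (< 2**31) from one pipeline seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(k)]
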