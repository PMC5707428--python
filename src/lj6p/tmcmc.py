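"""Transitional Markov Chain Monte Carlo with model-evidence estimation.

TMCMC tempers from the prior to the posterior through intermediate
distributions proportional to ``prior * likelihood**p_j`` with exponents
0 = p_0 < p_1 < ... < p_J = 1.  Each exponent increment is chosen so the
coefficient of variation of the incremental importance weights hits a
target (default 1.0), by bisection.  The log-evidence accumulates as the
sum over stages of the log mean incremental weight.

Within a stage, leaders are drawn by multinomial resampling; each unique
leader then runs a Gaussian random-walk Metropolis-Hastings chain whose
length equals its resampling multiplicity (one MH step per resampled chain
position), with proposal covariance ``beta**2`` times the weighted sample
covariance of the stage.  Every post-step chain state is emitted as one
sample, so the population size is constant across stages.  Proposals
leaving the prior support are rejected, which truncates the posterior
correctly.

All randomness flows from a single root seed through one generator in a
fixed call order, so identical seed + config gives bit-identical ensembles.
Likelihood evaluations within a chain sub-step are batched and
order-independent.

An optional kriging surrogate (see :mod:`lj6p.surrogate`) may intercept
log-likelihood evaluations; every rejected surrogate query triggers exactly
one true evaluation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import (
    DegenerateLikelihoodError,
    InvalidInputError,
    NonConvergenceError,
)
from . import surrogate as _surrogate
from .likelihood import PriorSpec
from .surrogate import SurrogateConfig, SurrogateStats


@dataclass(frozen=True)
class TMCMCConfig:
    """Sampler sizes and stage-control settings.

    ``n_samples`` per tempering stage (2000 for the 3+1-parameter 6-12
    model, 4000 when the exponent p is inferred); ``target_cov`` the
    coefficient-of-variation target for incremental weights; ``beta`` the
    random-walk proposal scaling; ``chain_steps`` the number of MH steps a
    chain takes per emitted state (more steps per stage equilibrate the
    population better against sharply peaked likelihoods, at proportional
    evaluation cost).
    """

    n_samples: int = 2000
    target_cov: float = 1.0
    beta: float = 0.2
    chain_steps: int = 3
    max_stages: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 100:
            raise InvalidInputError("n_samples must be >= 100")
        if not 0 < self.beta <= 1:
            raise InvalidInputError("beta must be in (0, 1]")
        if not self.target_cov > 0:
            raise InvalidInputError("target_cov must be > 0")
        if self.chain_steps < 1:
            raise InvalidInputError("chain_steps must be >= 1")


@dataclass
class PosteriorEnsemble:
    """Equal-weight posterior draws with log-densities and evidence."""

    samples: np.ndarray  # (n, d)
    param_names: tuple[str, ...]
    log_priors: np.ndarray
    log_likelihoods: np.ndarray
    log_evidence: float
    stage_exponents: list[float]
    seed: int
    config: TMCMCConfig | None = None
    n_true_evaluations: int | None = None
    surrogate_stats: dict | None = None

    def __post_init__(self):
        ex = self.stage_exponents
        if not ex or ex[0] != 0.0 or ex[-1] != 1.0 or np.any(np.diff(ex) <= 0):
            raise InvalidInputError(
                "stage_exponents must rise strictly from 0 to 1"
            )
        if not np.isfinite(self.log_evidence):
            raise InvalidInputError("log_evidence must be finite")

    def __len__(self) -> int:
        return self.samples.shape[0]


def next_exponent(current: float, log_likelihoods, target_cov: float = 1.0) -> float:
    """Largest admissible next tempering exponent.

    Finds the largest ``dp <= 1 - current`` such that the coefficient of
    variation (sample std / mean) of the weights
    ``exp(dp * (ll - max(ll)))`` does not exceed ``target_cov``, by
    bisection to an absolute tolerance of 1e-10.  Returns 1.0 outright when
    the full remaining step already satisfies the bound.  When the
    log-likelihood spread is so extreme that the admissible step is below
    the absolute tolerance (early stages of very sharp posteriors), the
    search switches to a geometric descent with relative refinement so the
    schedule always makes strictly positive progress.
    """
    if not current < 1.0:
        raise InvalidInputError("current exponent must be < 1")
    ll = np.asarray(log_likelihoods, dtype=float)
    centred = ll - np.max(ll[np.isfinite(ll)])

    def cov(dp: float) -> float:
        with np.errstate(over="ignore"):
            w = np.exp(dp * centred)
        m = w.mean()
        if m == 0:
            return np.inf
        return w.std(ddof=1) / m

    dp_max = 1.0 - current
    if cov(dp_max) <= target_cov:
        return 1.0
    lo, hi = 0.0, dp_max
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if cov(mid) <= target_cov:
            lo = mid
        else:
            hi = mid
    if lo == 0.0:
        # admissible step below absolute tolerance: geometric descent
        d = hi
        while d > 1e-300 and cov(d) > target_cov:
            d *= 0.5
        if d <= 1e-300:
            # weights degenerate for any positive step (e.g. mostly-zero
            # likelihood support); take the smallest resolvable step
            return current + hi
        lo, hi = d, 2.0 * d
        while hi - lo > 1e-3 * lo:
            mid = 0.5 * (lo + hi)
            if cov(mid) <= target_cov:
                lo = mid
            else:
                hi = mid
    return current + lo


class _SurrogateState:
    """Archive of true objective evaluations plus accounting."""

    def __init__(self, config: SurrogateConfig):
        self.config = config
        self.x: list[np.ndarray] = []
        self.y: list[float] = []
        self.stats = SurrogateStats()
        self._arch = None

    def add(self, X, y):
        for row, val in zip(np.atleast_2d(X), np.atleast_1d(y)):
            if np.isfinite(val):
                self.x.append(np.asarray(row, dtype=float))
                self.y.append(float(val))
        self._arch = None

    def archive(self):
        if self._arch is None:
            if not self.x:
                self._arch = (np.zeros((0, 0)), np.zeros(0))
            else:
                self._arch = (np.vstack(self.x), np.asarray(self.y))
        return self._arch


def _evaluate_with_surrogate(cand, chain_ids, positions, inside, dom_lo, dom_hi,
                             log_likelihood, state: _SurrogateState, box_cache: dict):
    """Surrogate-mediated batch evaluation of candidate log-likelihoods.

    ``box_cache`` maps chain id -> (leader position bytes, KrigingBox); a
    chain's box is rebuilt whenever its leader has moved.
    """
    n = cand.shape[0]
    ll_c = np.full(n, -np.inf)
    arch_x, arch_y = state.archive()
    need_true: list[int] = []
    for j in np.flatnonzero(inside):
        cid = int(chain_ids[j])
        key = positions[j].tobytes()
        cached = box_cache.get(cid)
        if cached is None or cached[0] != key:
            box = _surrogate.build_box(
                positions[j], dom_lo, dom_hi, arch_x, arch_y, state.config
            )
            box_cache[cid] = (key, box)
        else:
            box = cached[1]
        if not box.contains(cand[j]):
            state.stats.outside_box += 1
            need_true.append(j)
            continue
        dec = _surrogate.predict(box, cand[j], observed_values=arch_y)
        state.stats.record(dec)
        if dec.accepted:
            ll_c[j] = dec.value
        else:
            need_true.append(j)
    if need_true:
        idx = np.asarray(need_true)
        vals = np.asarray(log_likelihood(cand[idx]), dtype=float)
        ll_c[idx] = vals
        state.stats.true_evaluations += len(need_true)
        state.add(cand[idx], vals)
    return ll_c


def run_tmcmc(log_prior, log_likelihood, support: PriorSpec, config: TMCMCConfig,
              surrogate: SurrogateConfig | None = None,
              sample_prior=None,
              param_names: tuple[str, ...] | None = None) -> PosteriorEnsemble:
    """Sample a posterior and estimate its log-evidence.

    Parameters
    ----------
    log_prior, log_likelihood : callable
        Batched log-densities mapping an ``(n, d)`` array to ``(n,)``.
    support : PriorSpec
        Box support; proposals outside are rejected, and (absent a custom
        ``sample_prior``) the initial population is uniform over it.
    surrogate : SurrogateConfig, optional
        Enable kriging interception of likelihood evaluations.
    sample_prior : callable(rng, n) -> (n, d), optional
        Prior sampler for non-uniform priors; must respect ``support``.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_samples, support.dim
    names = param_names if param_names is not None else support.names

    X = sample_prior(rng, n) if sample_prior is not None else support.sample(rng, n)
    X = np.asarray(X, dtype=float)
    lp = np.asarray(log_prior(X), dtype=float)
    ll = np.asarray(log_likelihood(X), dtype=float)
    if not np.any(np.isfinite(ll)):
        raise DegenerateLikelihoodError(
            "all prior samples have -inf log-likelihood"
        )

    state = None
    if surrogate is not None and surrogate.enabled:
        state = _SurrogateState(surrogate)
        state.add(X, ll)
        state.stats.true_evaluations += n

    log_z = 0.0
    exponents = [0.0]
    p_j = 0.0
    eye_jitter = 1e-12 * np.eye(d)

    for _ in range(config.max_stages):
        p_next = next_exponent(p_j, ll, config.target_cov)
        dp = p_next - p_j
        finite = np.isfinite(ll)
        ll_max = np.max(ll[finite])
        a = np.where(finite, dp * (ll - ll_max), -np.inf)
        log_z += logsumexp(a) - np.log(n) + dp * ll_max
        w = np.exp(a - logsumexp(a))  # normalized weights

        mu = w @ X
        Xc = X - mu
        cov = (Xc * w[:, None]).T @ Xc
        prop_cov = config.beta ** 2 * cov + eye_jitter
        try:
            chol = np.linalg.cholesky(prop_cov)
        except np.linalg.LinAlgError:
            chol = np.diag(np.sqrt(np.maximum(np.diag(prop_cov), 1e-24)))

        # Multinomial resampling; each unique leader runs an MH chain whose
        # length is its multiplicity, emitting every post-step state.
        counts = rng.multinomial(n, w)
        chains = np.flatnonzero(counts)
        remaining = counts[chains]
        pos = X[chains].copy()
        lp_cur = lp[chains].copy()
        ll_cur = ll[chains].copy()

        out_X = np.empty((n, d))
        out_lp = np.empty(n)
        out_ll = np.empty(n)
        filled = 0
        dom_lo, dom_hi = X.min(axis=0), X.max(axis=0)
        box_cache: dict = {}

        active = np.arange(len(chains))
        while active.size:
            k = active
            for _step in range(config.chain_steps):
                cand = pos[k] + rng.standard_normal((k.size, d)) @ chol.T
                inside = support.contains(cand)
                lp_c = np.full(k.size, -np.inf)
                if np.any(inside):
                    lp_c[inside] = np.asarray(log_prior(cand[inside]), dtype=float)
                inside &= np.isfinite(lp_c)

                if state is not None:
                    ll_c = _evaluate_with_surrogate(
                        cand, k, pos[k], inside, dom_lo, dom_hi,
                        log_likelihood, state, box_cache,
                    )
                else:
                    ll_c = np.full(k.size, -np.inf)
                    if np.any(inside):
                        ll_c[inside] = np.asarray(
                            log_likelihood(cand[inside]), dtype=float
                        )

                with np.errstate(invalid="ignore"):
                    log_alpha = p_next * (ll_c - ll_cur[k]) + lp_c - lp_cur[k]
                log_alpha = np.where(inside, log_alpha, -np.inf)
                accept = np.log(rng.random(k.size)) < log_alpha

                pos[k] = np.where(accept[:, None], cand, pos[k])
                lp_cur[k] = np.where(accept, lp_c, lp_cur[k])
                ll_cur[k] = np.where(accept, ll_c, ll_cur[k])

            m = k.size
            out_X[filled:filled + m] = pos[k]
            out_lp[filled:filled + m] = lp_cur[k]
            out_ll[filled:filled + m] = ll_cur[k]
            filled += m
            remaining[k] -= 1
            active = k[remaining[k] > 0]

        X, lp, ll = out_X, out_lp, out_ll

        p_j = p_next
        exponents.append(p_j)
        if p_j >= 1.0:
            break
    else:
        raise NonConvergenceError(
            f"tempering did not reach exponent 1 in {config.max_stages} stages "
            f"(reached {p_j:.4f})",
            partial={"samples": X, "exponents": exponents, "log_evidence": log_z},
        )

    return PosteriorEnsemble(
        samples=X,
        param_names=tuple(names),
        log_priors=lp,
        log_likelihoods=ll,
        log_evidence=float(log_z),
        stage_exponents=exponents,
        seed=config.seed,
        config=config,
        n_true_evaluations=None if state is None else state.stats.true_evaluations,
        surrogate_stats=None if state is None else state.stats.as_dict(),
    )


def mpv(ensemble: PosteriorEnsemble) -> np.ndarray:
    """Most probable value: the sample maximizing log_prior + log_likelihood.

    Ties break toward the lowest sample index.
    """
    if len(ensemble) == 0:
        raise InvalidInputError("empty ensemble")
    score = ensemble.log_priors + ensemble.log_likelihoods
    return ensemble.samples[int(np.argmax(score))].copy()


def quantiles(ensemble: PosteriorEnsemble, which) -> np.ndarray:
    """Per-parameter empirical quantiles with linear interpolation.

    Returns an array of shape ``(len(which), d)``.
    """
    if len(ensemble) == 0:
        raise InvalidInputError("empty ensemble")
    levels = np.asarray(which, dtype=float)
    if np.any((levels <= 0) | (levels >= 1)):
        raise InvalidInputError("quantile levels must lie in (0, 1)")
    return np.quantile(ensemble.samples, levels, axis=0)


# -- persistence --------------------------------------------------------------

def save_ensemble(ensemble: PosteriorEnsemble, basepath) -> None:
    """Write ``<basepath>.csv`` (samples) and ``<basepath>.json`` (sidecar)."""
    basepath = str(basepath)
    df = pd.DataFrame(ensemble.samples, columns=list(ensemble.param_names))
    df["log_prior"] = ensemble.log_priors
    df["log_likelihood"] = ensemble.log_likelihoods
    df.to_csv(basepath + ".csv", index=False)  # shortest-repr floats round-trip
    sidecar = {
        "log_evidence": ensemble.log_evidence,
        "stage_exponents": list(ensemble.stage_exponents),
        "seed": ensemble.seed,
        "param_names": list(ensemble.param_names),
        "config": None if ensemble.config is None else dataclasses.asdict(ensemble.config),
        "n_true_evaluations": ensemble.n_true_evaluations,
        "surrogate_stats": ensemble.surrogate_stats,
    }
    with open(basepath + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_ensemble(basepath) -> PosteriorEnsemble:
    """Read an ensemble written by :func:`save_ensemble`."""
    basepath = str(basepath)
    df = pd.read_csv(basepath + ".csv", float_precision="round_trip")
    with open(basepath + ".json") as fh:
        sidecar = json.load(fh)
    names = tuple(sidecar["param_names"])
    cfg = sidecar.get("config")
    return PosteriorEnsemble(
        samples=df[list(names)].to_numpy(),
        param_names=names,
        log_priors=df["log_prior"].to_numpy(),
        log_likelihoods=df["log_likelihood"].to_numpy(),
        log_evidence=float(sidecar["log_evidence"]),
        stage_exponents=[float(x) for x in sidecar["stage_exponents"]],
        seed=int(sidecar["seed"]),
        config=None if cfg is None else TMCMCConfig(**cfg),
        n_true_evaluations=sidecar.get("n_true_evaluations"),
        surrogate_stats=sidecar.get("surrogate_stats"),
    )
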