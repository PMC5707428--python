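"""Two-level hierarchical Bayesian inference across datasets.

Stage 1 calibrates each dataset independently under the base uniform prior.
Stage 2 samples the hyper-parameter posterior p(psi | all data) with TMCMC,
using a self-normalized importance-sampling estimate of the marginal
likelihood built from the stage-1 ensembles:

    log p(d_i | psi) ~= log Z_i + log( (1/N) sum_k  p(theta_ik | psi)
                                                  / p(theta_ik | base) )

(the stage-1 samples theta_ik are draws from the base-prior posterior, so
reweighting them by the prior ratio marginalizes theta without re-running
the forward model).  Stage 3 refreshes each per-dataset posterior by
resampling its stage-1 ensemble with weights proportional to the prior
ratio averaged over the full psi posterior — marginalizing psi rather than
plugging in its most probable value.

The noise scale sigma_n is deliberately left out of the hierarchical tie:
it is condition-specific measurement/model error, so each dataset keeps its
base uniform prior on sigma_n and only the physical parameters are pooled.
Effective sample sizes of every importance-sampling step are recorded so
estimator degeneracy is visible rather than silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .calibrate import calibrate
from .exceptions import InvalidInputError
from .forward_models import Dataset
from .likelihood import (
    ConditionalPriorFamily,
    MODEL_LJ6_P,
    PriorSpec,
    default_prior,
    get_family,
    physical_prior,
)
from .tmcmc import PosteriorEnsemble, TMCMCConfig, run_tmcmc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HBConfig:
    """Sampler sizes and guards for the three hierarchical stages."""

    stage1_samples: int | None = None  # default: per-model TMCMC default
    hyper_samples: int = 1000
    seed: int = 0
    ess_floor: float = 50.0
    max_stages: int = 60


@dataclass
class HBResult:
    """Hyper posterior, per-dataset stage-1 and refreshed ensembles, ESS."""

    hyper_ensemble: PosteriorEnsemble
    stage1: list[PosteriorEnsemble]
    refreshed: list[PosteriorEnsemble]
    ess: list[float]
    family_name: str
    warnings: list[str] = field(default_factory=list)


def _derive_seed(root: int, k: int) -> int:
    return int((root * 1_000_003 + 7919 * k + 1) % (2 ** 31))


def _physical_columns(ensemble: PosteriorEnsemble) -> np.ndarray:
    idx = [i for i, n in enumerate(ensemble.param_names) if n != "sigma_n"]
    return ensemble.samples[:, idx]


def hyper_log_likelihood(psi, stage1: list[PosteriorEnsemble],
                         family: ConditionalPriorFamily,
                         base_prior: PriorSpec) -> float:
    """Importance-sampling estimate of sum_i log p(d_i | psi).

    Exact up to a psi-independent constant; returns -inf (with a logged
    warning) when the psi support is disjoint from every stage-1 sample of
    some dataset.
    """
    psi = np.asarray(psi, dtype=float)
    if not family.admissible(psi):
        raise InvalidInputError(f"inadmissible psi for family {family.name}")
    out = _hyper_ll_batch(psi[None, :], stage1, family, base_prior)
    val = float(out[0])
    if not np.isfinite(val):
        logger.warning("hyper likelihood -inf: psi support disjoint from stage-1 samples")
    return val


def _hyper_ll_batch(psis, stage1, family, base_prior) -> np.ndarray:
    """Vectorized hyper log-likelihood over psis (m, n_psi) -> (m,)."""
    psis = np.atleast_2d(np.asarray(psis, dtype=float))
    m = psis.shape[0]
    phys_log_vol = physical_prior(base_prior).log_volume
    total = np.zeros(m)
    for ens in stage1:
        theta_phys = _physical_columns(ens)
        fam_lp = family.log_pdf_batch(theta_phys, psis)  # (m, k)
        # ratio to the uniform base density 1/V: log ratio = fam_lp + log V
        log_mean_ratio = logsumexp(fam_lp, axis=1) - np.log(theta_phys.shape[0]) \
            + phys_log_vol
        total += ens.log_evidence + log_mean_ratio
    return total


def _refresh_weights(ensemble: PosteriorEnsemble, psi_samples,
                     family: ConditionalPriorFamily) -> tuple[np.ndarray, float]:
    """Normalized stage-3 weights over stage-1 samples, plus their ESS."""
    theta_phys = _physical_columns(ensemble)
    fam_lp = family.log_pdf_batch(theta_phys, psi_samples)  # (m, k)
    m = fam_lp.shape[0]
    log_w = logsumexp(fam_lp, axis=0) - np.log(m)  # (k,) log mean over psi
    finite = np.isfinite(log_w)
    if not np.any(finite):
        raise InvalidInputError("all refresh weights are zero")
    log_w = log_w - logsumexp(log_w[finite])
    w = np.where(finite, np.exp(log_w), 0.0)
    w = w / w.sum()
    ess = float(1.0 / np.sum(w ** 2))
    return w, ess


def _resample_ensemble(ensemble: PosteriorEnsemble, w: np.ndarray,
                       rng: np.random.Generator) -> PosteriorEnsemble:
    n = len(ensemble)
    if np.ptp(w) < 1e-14 / n:
        idx = np.arange(n)  # uniform weights: refresh is the identity
    else:
        idx = rng.choice(n, size=n, p=w)
    return PosteriorEnsemble(
        samples=ensemble.samples[idx].copy(),
        param_names=ensemble.param_names,
        log_priors=ensemble.log_priors[idx].copy(),
        log_likelihoods=ensemble.log_likelihoods[idx].copy(),
        log_evidence=ensemble.log_evidence,
        stage_exponents=list(ensemble.stage_exponents),
        seed=ensemble.seed,
        config=ensemble.config,
    )


def run_hb(datasets: list[Dataset], model_tag: str = MODEL_LJ6_P,
           family: str | ConditionalPriorFamily = "independent_truncated_normal",
           config: HBConfig | None = None) -> HBResult:
    """Full three-stage hierarchical inference over a set of datasets."""
    if len(datasets) < 1:
        raise InvalidInputError("need at least one dataset")
    config = config or HBConfig()
    base_prior = default_prior(model_tag)
    if isinstance(family, str):
        family = get_family(family, physical_prior(base_prior))

    n1 = config.stage1_samples
    if n1 is None:
        n1 = 4000 if model_tag == MODEL_LJ6_P else 2000

    stage1 = []
    for i, ds in enumerate(datasets):
        cfg = TMCMCConfig(n_samples=n1, seed=_derive_seed(config.seed, i),
                          max_stages=config.max_stages)
        stage1.append(calibrate(ds, model_tag, config=cfg, prior=base_prior))

    psi_box = family.psi_prior()
    hyper_cfg = TMCMCConfig(
        n_samples=config.hyper_samples,
        seed=_derive_seed(config.seed, 10_000),
        max_stages=config.max_stages,
    )
    hyper_ens = run_tmcmc(
        family.psi_log_prior,
        lambda psis: _hyper_ll_batch(psis, stage1, family, base_prior),
        psi_box,
        hyper_cfg,
        param_names=family.psi_names,
    )

    warnings: list[str] = []
    refreshed, ess_list = [], []
    rng = np.random.default_rng(_derive_seed(config.seed, 20_000))
    for i, ens in enumerate(stage1):
        w, ess = _refresh_weights(ens, hyper_ens.samples, family)
        if ess < config.ess_floor:
            msg = f"dataset {i}: refresh ESS {ess:.1f} below floor {config.ess_floor}"
            logger.warning(msg)
            warnings.append(msg)
        refreshed.append(_resample_ensemble(ens, w, rng))
        ess_list.append(ess)

    return HBResult(
        hyper_ensemble=hyper_ens,
        stage1=stage1,
        refreshed=refreshed,
        ess=ess_list,
        family_name=family.name,
        warnings=warnings,
    )
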