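"""Reusable study drivers: the computations behind the analysis scripts.

Each function runs one self-contained numerical experiment from scratch —
conjugate-Gaussian evidence checks, parameter recovery on the gas-phase
dimer fixture, evidence-based model selection, hierarchical shrinkage, and
surrogate neutrality — and returns plain dictionaries of numbers.  Tests,
the command-line drivers under ``analysis/`` and the acceptance script all
call these, so every reported figure has exactly one implementation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calibrate import calibrate
from .hierarchical import HBConfig, run_hb
from .likelihood import MODEL_LJ6_12, MODEL_LJ6_P, PriorSpec
from .surrogate import SurrogateConfig
from .synthetic import (
    generate,
    hb_shrinkage_presets,
    model_selection_presets,
    argon_presets,
)
from .tmcmc import TMCMCConfig, mpv, quantiles, run_tmcmc

#: Analytic log-evidence of the 1-D conjugate check: standard-normal prior,
#: unit-variance Gaussian likelihood centred on the datum 0, so
#: Z = N(0 | 0, 2) = 1/(2*sqrt(pi)).
CONJUGATE_LOG_EVIDENCE = float(-np.log(2.0 * np.sqrt(np.pi)))

_HALF_LOG_2PI = 0.5 * float(np.log(2.0 * np.pi))


def _std_normal_logpdf(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(x)[:, 0]
    return -0.5 * x ** 2 - _HALF_LOG_2PI


def conjugate_log_evidence(likelihood_sd: float = 1.0) -> float:
    """Analytic log-evidence: N(0 | 0, 1 + sd^2) under the standard-normal prior."""
    return float(-0.5 * (np.log(2.0 * np.pi) + np.log(1.0 + likelihood_sd ** 2)))


def conjugate_evidence_trial(seed: int, n_samples: int = 2000,
                             surrogate: SurrogateConfig | None = None,
                             likelihood_sd: float = 1.0) -> float:
    """One TMCMC log-evidence estimate for the 1-D conjugate Gaussian model.

    Standard-normal prior; Gaussian likelihood of width ``likelihood_sd``
    centred on the datum 0.  Widths below 1 need several tempering stages,
    which is what exercises the surrogate path end to end.
    """
    support = PriorSpec(("x",), np.array([-10.0]), np.array([10.0]))

    def sample_prior(rng, n):
        # truncation to [-10, 10] has mass ~1e-23; clip for support safety
        return np.clip(rng.standard_normal((n, 1)), -10.0, 10.0)

    def log_lik(x):
        x = np.atleast_2d(x)[:, 0]
        return -0.5 * (x / likelihood_sd) ** 2 - _HALF_LOG_2PI - np.log(likelihood_sd)

    cfg = TMCMCConfig(n_samples=n_samples, seed=seed)
    ens = run_tmcmc(
        _std_normal_logpdf, log_lik, support, cfg,
        surrogate=surrogate, sample_prior=sample_prior,
    )
    return ens.log_evidence


def conjugate_evidence_study(n_seeds: int = 10, n_samples: int = 2000,
                             seed0: int = 0) -> dict:
    """Mean absolute log-evidence error over independent seeds."""
    estimates = [
        conjugate_evidence_trial(seed0 + k, n_samples) for k in range(n_seeds)
    ]
    errors = [abs(z - CONJUGATE_LOG_EVIDENCE) for z in estimates]
    return {
        "estimates": estimates,
        "analytic": CONJUGATE_LOG_EVIDENCE,
        "mean_abs_error": float(np.mean(errors)),
        "mean_estimate": float(np.mean(estimates)),
    }


def dimer_recovery_trial(seed: int, n_samples: int = 4000) -> dict:
    """Calibrate LJ 6-p on one realization of the gas-phase dimer fixture.

    Reports the posterior MPV and 5-95% interval of the repulsion exponent
    against the generating truth p = 12.703.
    """
    spec = replace(argon_presets()["dimer_Q"], seed=seed)
    data = generate(spec)
    cfg = TMCMCConfig(n_samples=n_samples, seed=seed)
    ens = calibrate(data, MODEL_LJ6_P, config=cfg)
    p_idx = ens.param_names.index("p")
    q05, q95 = quantiles(ens, [0.05, 0.95])[:, p_idx]
    b = mpv(ens)
    p_mpv = float(b[p_idx])
    p_true = spec.truth.lj.p
    sn_mpv = float(b[ens.param_names.index("sigma_n")])
    return {
        "p_true": p_true,
        "p_mpv": p_mpv,
        "p_q05": float(q05),
        "p_q95": float(q95),
        "covered": bool(q05 <= p_true <= q95),
        "mpv_error": abs(p_mpv - p_true),
        "sigma_n_mpv": sn_mpv,
        "sigma_n_factor": sn_mpv / spec.truth.sigma_n,
        "log_evidence": ens.log_evidence,
    }


def dimer_recovery_study(n_seeds: int = 20, n_samples: int = 4000,
                         seed0: int = 100) -> dict:
    """Coverage and MPV accuracy of p over repeated fixture realizations."""
    trials = [dimer_recovery_trial(seed0 + k, n_samples) for k in range(n_seeds)]
    return {
        "trials": trials,
        "n_seeds": n_seeds,
        "n_covered": sum(t["covered"] for t in trials),
        "n_mpv_within_1": sum(t["mpv_error"] <= 1.0 for t in trials),
        "n_sigma_n_within_2x": sum(
            0.5 <= t["sigma_n_factor"] <= 2.0 for t in trials
        ),
    }


def model_selection_trial(seed: int, truth: str,
                          n_samples_12: int = 2000,
                          n_samples_p: int = 4000) -> dict:
    """Evidence of LJ 6-12 vs LJ 6-p on one synthetic dimer realization.

    ``truth`` is ``"dimer_p12"`` (classical-potential ground truth) or
    ``"dimer_p65"`` (soft-repulsion ground truth).
    """
    spec = replace(model_selection_presets()[truth], seed=seed)
    data = generate(spec)
    ens12 = calibrate(data, MODEL_LJ6_12,
                      config=TMCMCConfig(n_samples=n_samples_12, seed=seed))
    ensp = calibrate(data, MODEL_LJ6_P,
                     config=TMCMCConfig(n_samples=n_samples_p, seed=seed + 1))
    return {
        "log_evidence_12": ens12.log_evidence,
        "log_evidence_p": ensp.log_evidence,
        "winner": MODEL_LJ6_12 if ens12.log_evidence >= ensp.log_evidence else MODEL_LJ6_P,
    }


def model_selection_study(n_seeds: int = 10, seed0: int = 300, **kw) -> dict:
    """Win counts for the two ground truths over repeated realizations."""
    p12 = [model_selection_trial(seed0 + 2 * k, "dimer_p12", **kw) for k in range(n_seeds)]
    p65 = [model_selection_trial(seed0 + 2 * k + 1, "dimer_p65", **kw) for k in range(n_seeds)]
    return {
        "n_seeds": n_seeds,
        "p12_truth_wins_12": sum(t["winner"] == MODEL_LJ6_12 for t in p12),
        "p65_truth_wins_p": sum(t["winner"] == MODEL_LJ6_P for t in p65),
        "p12_trials": p12,
        "p65_trials": p65,
    }


def hb_shrinkage_study(seed: int = 0, stage1_samples: int = 1500,
                       hyper_samples: int = 800,
                       family: str = "independent_truncated_normal") -> dict:
    """Hierarchical pooling on 3 informative + 1 weak dimer datasets.

    Measures the 5-95% epsilon interval of the weak dataset before and
    after the hierarchical refresh; pooling should narrow it.
    """
    specs = hb_shrinkage_presets()
    datasets = [generate(replace(s, seed=s.seed + seed)) for s in specs]
    cfg = HBConfig(stage1_samples=stage1_samples, hyper_samples=hyper_samples,
                   seed=seed)
    result = run_hb(datasets, MODEL_LJ6_P, family=family, config=cfg)
    weak = len(datasets) - 1
    eps_idx = result.stage1[weak].param_names.index("epsilon")

    def width(ens):
        q05, q95 = quantiles(ens, [0.05, 0.95])[:, eps_idx]
        return float(q95 - q05)

    w_before = width(result.stage1[weak])
    w_after = width(result.refreshed[weak])
    return {
        "eps_interval_stage1": w_before,
        "eps_interval_refreshed": w_after,
        "shrinkage_ratio": w_after / w_before,
        "ess": result.ess,
        "warnings": result.warnings,
    }


def surrogate_neutrality_study(n_seeds: int = 10, n_samples: int = 1000,
                               seed0: int = 700,
                               likelihood_sd: float = 0.2) -> dict:
    """Conjugate-Gaussian evidence with and without the kriging surrogate.

    The default likelihood width 0.2 forces a multi-stage tempering
    schedule, so surrogate-predicted log-likelihoods genuinely enter the
    stage weights, the exponent control and the MH accept/reject decisions.
    """
    on, off = [], []
    for k in range(n_seeds):
        seed = seed0 + k
        off.append(conjugate_evidence_trial(seed, n_samples,
                                            likelihood_sd=likelihood_sd))
        on.append(conjugate_evidence_trial(seed, n_samples,
                                           surrogate=SurrogateConfig(),
                                           likelihood_sd=likelihood_sd))
    gap = abs(float(np.mean(on)) - float(np.mean(off)))
    return {
        "with_surrogate": on,
        "without_surrogate": off,
        "mean_gap": gap,
        "analytic": conjugate_log_evidence(likelihood_sd),
    }
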