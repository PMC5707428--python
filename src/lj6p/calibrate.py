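"""Single-dataset calibration: glue between data, likelihood and sampler.

``calibrate`` runs TMCMC for one observable curve under either the LJ 6-12
or the LJ 6-p model with the package's default wide uniform prior boxes,
producing an equal-weight posterior ensemble over
(epsilon, sigma, [p], sigma_n) plus the model log-evidence.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError
from .forward_models import Dataset, dilute_rdf_curves, dimer_energy_curves
from .likelihood import (
    MODEL_LJ6_12,
    MODEL_LJ6_P,
    PriorSpec,
    default_prior,
    gaussian_log_likelihood_batch,
)
from .surrogate import SurrogateConfig
from .tmcmc import PosteriorEnsemble, TMCMCConfig, run_tmcmc


def dataset_log_likelihood(dataset: Dataset, model_tag: str):
    """Batched theta -> log-likelihood map for one dataset.

    Rows of theta are (epsilon, sigma, [p], sigma_n); the curve model is
    chosen by the dataset kind (untruncated dimer energy, or the truncated
    dilute-gas RDF stand-in).
    """
    if model_tag not in (MODEL_LJ6_12, MODEL_LJ6_P):
        raise InvalidInputError(f"unknown model_tag {model_tag!r}")
    has_p = model_tag == MODEL_LJ6_P
    r_grid = dataset.r_grid
    data = dataset.values
    temperature = dataset.condition.temperature
    if dataset.kind == "rdf" and temperature is None:
        raise InvalidInputError("rdf datasets need a temperature")

    def log_likelihood(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        eps, sig = theta[:, 0], theta[:, 1]
        p = theta[:, 2] if has_p else np.full(theta.shape[0], 12.0)
        sigma_n = theta[:, -1]
        if dataset.kind == "dimer_energy":
            curves = dimer_energy_curves(eps, sig, p, r_grid)
        else:
            curves = dilute_rdf_curves(eps, sig, p, temperature, r_grid)
        return gaussian_log_likelihood_batch(data, curves, sigma_n)

    return log_likelihood


def calibrate(dataset: Dataset, model_tag: str, config: TMCMCConfig | None = None,
              prior: PriorSpec | None = None,
              surrogate: SurrogateConfig | None = None) -> PosteriorEnsemble:
    """Calibrate one dataset under one model; returns the posterior ensemble.

    Defaults: the model's standard prior box and 2000 (LJ 6-12) or 4000
    (LJ 6-p) samples per tempering stage.
    """
    prior = prior if prior is not None else default_prior(model_tag)
    if config is None:
        n = 4000 if model_tag == MODEL_LJ6_P else 2000
        config = TMCMCConfig(n_samples=n)
    log_lik = dataset_log_likelihood(dataset, model_tag)
    return run_tmcmc(
        prior.log_pdf, log_lik, prior, config,
        surrogate=surrogate, param_names=prior.names,
    )
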