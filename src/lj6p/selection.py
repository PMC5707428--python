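"""Evidence-based model comparison and robust posterior prediction.

Model selection between the LJ 6-12 and LJ 6-p potentials uses the ratio
of model evidences (Bayes factor), with bookkeeping kept in log space.
Robust prediction propagates the posterior parameter uncertainty through a
forward model: the quantity of interest is evaluated at the most probable
value and at a posterior subsample, and reported with pointwise 5-95%
quantile bands.  Prediction quality against a reference is summarized by
the mean squared relative error

    Delta_g = (1/N) * sum_k ((g_k - r_k) / r_k)**2

over the N conditions, and RDF curves by the mean over conditions of the
mean squared error between curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, PredictionError
from .forward_models import Condition, ForwardModel
from .likelihood import ParamVector
from .tmcmc import PosteriorEnsemble, mpv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelComparison:
    """Two models' log-evidences and their Bayes factor."""

    label_1: str
    label_2: str
    log_evidence_1: float
    log_evidence_2: float

    @property
    def log_bayes_factor(self) -> float:
        """log BF(2 over 1) = E2 - E1, exact in log space."""
        return self.log_evidence_2 - self.log_evidence_1

    @property
    def bayes_factor(self) -> float:
        return float(np.exp(self.log_bayes_factor))


def bayes_factor(e1: float, e2: float, label_1: str = "model_1",
                 label_2: str = "model_2") -> ModelComparison:
    """Compare two models by log-evidence; BF = exp(e2 - e1)."""
    if not (np.isfinite(e1) and np.isfinite(e2)):
        raise InvalidInputError("log-evidences must be finite")
    return ModelComparison(label_1, label_2, float(e1), float(e2))


@dataclass(frozen=True)
class PredictionSummary:
    """MPV curve with pointwise posterior quantile bands for one condition."""

    condition: Condition
    r_grid: np.ndarray
    mpv_curve: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    n_draws: int
    n_failures: int
    reference: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.q05 > self.q95):
            raise InvalidInputError("q05 must not exceed q95")


def robust_predict(ensemble: PosteriorEnsemble, model: ForwardModel,
                   condition: Condition, r_grid, subsample: int = 100,
                   seed: int = 0,
                   reference=None) -> PredictionSummary:
    """Propagate posterior uncertainty through a forward model.

    Evaluates the model at the ensemble MPV and at ``subsample`` posterior
    draws (with replacement if ``subsample`` exceeds the ensemble size) and
    reports the MPV curve with pointwise 5% and 95% quantiles across draws.
    Individual draw failures are dropped with a logged count; more than 50%
    failures aborts with :class:`PredictionError`.
    """
    if len(ensemble) == 0:
        raise InvalidInputError("empty ensemble")
    r_grid = np.asarray(r_grid, dtype=float)
    model_tag = "LJ6_p" if "p" in ensemble.param_names else "LJ6_12"

    def eval_theta(row) -> np.ndarray | None:
        try:
            pv = ParamVector.from_array(row, model_tag)
            curve = np.asarray(model.evaluate(pv.lj, condition, r_grid), dtype=float)
            if curve.shape != r_grid.shape or not np.all(np.isfinite(curve)):
                return None
            return curve
        except Exception:
            return None

    mpv_curve = eval_theta(mpv(ensemble))
    if mpv_curve is None:
        raise PredictionError("forward model failed at the MPV")

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ensemble), size=subsample, replace=True)
    curves, failures = [], 0
    for i in idx:
        c = eval_theta(ensemble.samples[i])
        if c is None:
            failures += 1
        else:
            curves.append(c)
    if failures:
        logger.warning("robust_predict: %d/%d draw evaluations failed", failures, subsample)
    if failures > 0.5 * subsample:
        raise PredictionError(f"{failures}/{subsample} forward evaluations failed")
    stack = np.vstack(curves)
    q05, q95 = np.quantile(stack, [0.05, 0.95], axis=0)
    return PredictionSummary(
        condition=condition,
        r_grid=r_grid,
        mpv_curve=mpv_curve,
        q05=q05,
        q95=q95,
        n_draws=len(curves),
        n_failures=failures,
        reference=None if reference is None else np.asarray(reference, dtype=float),
    )


def prediction_error(predicted, reference) -> float:
    """Mean squared relative error of scalar predictions across conditions."""
    g = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if g.shape != r.shape or g.ndim != 1 or g.size < 1:
        raise InvalidInputError("predicted and reference must be equal-length 1-D, N >= 1")
    if np.any(r == 0):
        raise InvalidInputError("reference values must be nonzero")
    return float(np.mean(((g - r) / r) ** 2))


def rdf_error(predicted_curves, reference_curves) -> float:
    """Mean over conditions of the MSE between predicted and reference curves."""
    if len(predicted_curves) != len(reference_curves) or len(predicted_curves) == 0:
        raise InvalidInputError("need matched, non-empty condition sets")
    errs = []
    for g, r in zip(predicted_curves, reference_curves):
        g = np.asarray(g, dtype=float)
        r = np.asarray(r, dtype=float)
        if g.shape != r.shape:
            raise InvalidInputError("curve grid mismatch between predicted and reference")
        errs.append(np.mean((g - r) ** 2))
    return float(np.mean(errs))
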