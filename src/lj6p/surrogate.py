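"""Local ordinary-kriging surrogate for the log-likelihood inside TMCMC.

For each Markov-chain leader a kriging interpolant is built from the truly
evaluated points inside the leader's bounding box, whose per-dimension width
is a quarter of the current sampling domain (clipped to the domain).  A
surrogate prediction replaces a true forward evaluation only when all of the
following hold:

1. the box holds at least ``2*dim + 1`` training points,
2. the kriging standard error is at most 5% of |predicted value|, and
3. the prediction lies within the 5-95% quantile band of all true objective
   values observed so far.

Any rejected prediction falls back to exactly one true evaluation; a
singular correlation matrix is treated as "too few points", never raised to
the sampler.  The surrogate operates on the scalar objective the sampler
consumes (the log-likelihood), not on raw observable curves.

The interpolant is ordinary kriging with a squared-exponential correlation,
a small relative nugget, and a single length-scale (in box-scaled
coordinates) chosen by maximizing the concentrated kriging marginal
likelihood over a fixed grid.  The standard error includes the
mean-estimation term of the ordinary-kriging variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

#: Fraction of the current domain width used for the leader's box.
BOX_FRACTION = 0.25

#: Candidate length-scales in box-scaled coordinates.
_DEFAULT_LENGTHSCALES = tuple(np.geomspace(0.05, 2.0, 10))


@dataclass(frozen=True)
class SurrogateConfig:
    """Tunable knobs of the kriging surrogate.

    ``rel_error`` is the acceptance threshold on predicted_error / |value|;
    ``band`` the quantile band of observed true objectives a prediction must
    fall into; ``max_train`` caps the training set at the points nearest the
    leader (keeps per-leader fits O(1)); ``nugget_rel`` is the relative
    nugget on the correlation diagonal.
    """

    enabled: bool = True
    rel_error: float = 0.05
    band: tuple[float, float] = (0.05, 0.95)
    max_train: int = 32
    nugget_rel: float = 1e-8
    lengthscales: tuple[float, ...] = _DEFAULT_LENGTHSCALES

    def min_points(self, dim: int) -> int:
        return 2 * dim + 1


@dataclass(frozen=True)
class SurrogateDecision:
    """Outcome of one surrogate query."""

    value: float
    predicted_error: float
    accepted: bool
    reason: str  # ok | error_gt_5pct | outside_quantile_band | too_few_points

    def __post_init__(self):
        if self.accepted and self.reason != "ok":
            raise ValueError("accepted decisions must have reason 'ok'")


class _KrigingFit:
    """Factorized ordinary-kriging model over box-scaled coordinates."""

    def __init__(self, u, y, lengthscale, nugget_rel):
        self.u = u
        self.ls = lengthscale
        n = u.shape[0]
        sq = _sqdist(u, u)
        R = np.exp(-0.5 * sq / lengthscale ** 2)
        R[np.diag_indices(n)] += nugget_rel
        self._cf = cho_factor(R, lower=True)
        ones = np.ones(n)
        self.Rinv_1 = cho_solve(self._cf, ones)
        one_Rinv_one = float(ones @ self.Rinv_1)
        self.mu = float(ones @ cho_solve(self._cf, y)) / one_Rinv_one
        resid = y - self.mu
        self.Rinv_resid = cho_solve(self._cf, resid)
        self.sigma2 = max(float(resid @ self.Rinv_resid) / n, 1e-300)
        self.one_Rinv_one = one_Rinv_one
        L = self._cf[0]
        self.log_det = 2.0 * float(np.sum(np.log(np.diag(L))))
        self.concentrated_ll = -0.5 * (n * np.log(self.sigma2) + self.log_det)
        self.nugget_rel = nugget_rel

    def predict(self, u_star) -> tuple[float, float]:
        sq = np.sum((self.u - u_star[None, :]) ** 2, axis=1)
        r = np.exp(-0.5 * sq / self.ls ** 2)
        Rinv_r = cho_solve(self._cf, r)
        mean = self.mu + float(r @ self.Rinv_resid)
        one_minus = 1.0 - float(r @ self.Rinv_1)
        var = self.sigma2 * (
            1.0 + self.nugget_rel - float(r @ Rinv_r) + one_minus ** 2 / self.one_Rinv_one
        )
        return mean, float(np.sqrt(max(var, 0.0)))


def _sqdist(a, b):
    return np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)


@dataclass
class KrigingBox:
    """A leader's local box with its training points and (lazy) fit."""

    leader: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    train_x: np.ndarray
    train_y: np.ndarray
    config: SurrogateConfig = field(default_factory=SurrogateConfig)
    _fit: object = field(default=None, repr=False)
    _fit_failed: bool = field(default=False, repr=False)

    @property
    def n_train(self) -> int:
        return self.train_x.shape[0]

    def contains(self, point) -> bool:
        point = np.asarray(point, dtype=float)
        return bool(np.all(point >= self.lower) and np.all(point <= self.upper))

    def fit(self):
        """Fit (once) by maximizing the concentrated likelihood over the grid."""
        if self._fit is not None or self._fit_failed:
            return self._fit
        widths = np.where(self.upper > self.lower, self.upper - self.lower, 1.0)
        u = (self.train_x - self.lower) / widths
        y = self.train_y
        best = None
        for ls in self.config.lengthscales:
            try:
                cand = _KrigingFit(u, y, ls, self.config.nugget_rel)
            except (LinAlgError, np.linalg.LinAlgError, ValueError):
                continue
            if best is None or cand.concentrated_ll > best.concentrated_ll:
                best = cand
        if best is None:
            self._fit_failed = True
            return None
        self._widths = widths
        self._fit = best
        return best


def build_box(leader, domain_lower, domain_upper, evaluated_x, evaluated_y,
              config: SurrogateConfig | None = None) -> KrigingBox:
    """Quarter-domain box centred at the leader, clipped to the domain.

    The training set is every truly evaluated point inside the box, capped
    at the ``config.max_train`` points nearest the leader.
    """
    config = config or SurrogateConfig()
    leader = np.asarray(leader, dtype=float)
    dlo = np.asarray(domain_lower, dtype=float)
    dhi = np.asarray(domain_upper, dtype=float)
    half = 0.5 * BOX_FRACTION * (dhi - dlo)
    lower = np.clip(leader - half, dlo, dhi)
    upper = np.clip(leader + half, dlo, dhi)
    x = np.asarray(evaluated_x, dtype=float)
    y = np.asarray(evaluated_y, dtype=float)
    if x.size == 0:
        x = x.reshape(0, leader.size)
        inside = np.zeros(0, dtype=bool)
    else:
        x = np.atleast_2d(x)
        inside = np.all((x >= lower) & (x <= upper), axis=1)
    xi, yi = x[inside], y[inside]
    if xi.shape[0] > config.max_train:
        d2 = np.sum((xi - leader[None, :]) ** 2, axis=1)
        keep = np.argsort(d2, kind="stable")[: config.max_train]
        xi, yi = xi[keep], yi[keep]
    return KrigingBox(leader=leader, lower=lower, upper=upper,
                      train_x=xi, train_y=yi, config=config)


def predict(box: KrigingBox, point, observed_values=None) -> SurrogateDecision:
    """Query the box surrogate at a point inside its bounds.

    ``observed_values`` is the pool of all true objective values seen so far;
    it defines the quantile band of acceptance rule (3).  Omitting it skips
    the band check (used by low-level tests only).
    """
    point = np.asarray(point, dtype=float)
    cfg = box.config
    dim = point.size
    if box.n_train < cfg.min_points(dim):
        return SurrogateDecision(np.nan, np.inf, False, "too_few_points")
    fit = box.fit()
    if fit is None:
        return SurrogateDecision(np.nan, np.inf, False, "too_few_points")
    u_star = (point - box.lower) / box._widths
    mean, se = fit.predict(u_star)
    if not np.isfinite(mean) or not np.isfinite(se):
        return SurrogateDecision(np.nan, np.inf, False, "too_few_points")
    if se > cfg.rel_error * abs(mean):
        # values near zero auto-reject: the relative rule has no safe scale
        return SurrogateDecision(mean, se, False, "error_gt_5pct")
    if observed_values is not None and len(observed_values) > 0:
        q_lo, q_hi = np.quantile(np.asarray(observed_values, float), cfg.band)
        if not (q_lo <= mean <= q_hi):
            return SurrogateDecision(mean, se, False, "outside_quantile_band")
    return SurrogateDecision(mean, se, True, "ok")


@dataclass
class SurrogateStats:
    """Per-run accounting of surrogate activity."""

    queries: int = 0
    accepted: int = 0
    rejected_error: int = 0
    rejected_band: int = 0
    rejected_few: int = 0
    outside_box: int = 0
    true_evaluations: int = 0

    def record(self, decision: SurrogateDecision):
        self.queries += 1
        if decision.accepted:
            self.accepted += 1
        elif decision.reason == "error_gt_5pct":
            self.rejected_error += 1
        elif decision.reason == "outside_quantile_band":
            self.rejected_band += 1
        else:
            self.rejected_few += 1

    def as_dict(self) -> dict:
        return dict(self.__dict__)
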