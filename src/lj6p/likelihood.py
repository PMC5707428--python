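"""Gaussian data model, uniform priors, and conditional prior families.

The data model is i.i.d. Gaussian per bin with a single inferred noise scale
``sigma_n`` per dataset (covariance ``sigma_n**2 * I``):

    log L = -(N/2) * log(2*pi*sigma_n**2) - SSE / (2*sigma_n**2).

Base priors are uniform boxes; the hierarchical layer uses a conditional
prior family p(theta | psi) over the *physical* parameters (epsilon, sigma
and, for the 6-p model, p), with sigma_n kept on its per-dataset base prior.
Two families are provided: a movable uniform box and independent truncated
normals (the default: smooth shrinkage that lets information flow between
datasets).  Every family density is renormalized over the global base box,
so it integrates to 1 for every admissible psi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .exceptions import InvalidInputError
from .forward_models import Dataset
from .potential import LJParams

MODEL_LJ6_12 = "LJ6_12"
MODEL_LJ6_P = "LJ6_p"

PARAM_NAMES = {
    MODEL_LJ6_12: ("epsilon", "sigma", "sigma_n"),
    MODEL_LJ6_P: ("epsilon", "sigma", "p", "sigma_n"),
}

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ParamVector:
    """Inferred quantities theta = (epsilon, sigma, [p], sigma_n)."""

    lj: LJParams
    sigma_n: float
    model_tag: str

    def __post_init__(self):
        if self.model_tag not in PARAM_NAMES:
            raise InvalidInputError(f"unknown model_tag {self.model_tag!r}")
        if not (np.isfinite(self.sigma_n) and self.sigma_n > 0):
            raise InvalidInputError(f"sigma_n must be > 0, got {self.sigma_n}")
        if self.model_tag == MODEL_LJ6_12 and self.lj.p != 12.0:
            raise InvalidInputError("LJ6_12 parameter vectors must have p == 12")

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.model_tag]

    def to_array(self) -> np.ndarray:
        if self.model_tag == MODEL_LJ6_P:
            return np.array([self.lj.epsilon, self.lj.sigma, self.lj.p, self.sigma_n])
        return np.array([self.lj.epsilon, self.lj.sigma, self.sigma_n])

    @classmethod
    def from_array(cls, arr, model_tag: str) -> "ParamVector":
        arr = np.asarray(arr, dtype=float)
        if model_tag == MODEL_LJ6_P:
            if arr.size != 4:
                raise InvalidInputError("LJ6_p vectors have 4 entries")
            lj = LJParams(epsilon=arr[0], sigma=arr[1], p=arr[2])
            return cls(lj=lj, sigma_n=float(arr[3]), model_tag=model_tag)
        if arr.size != 3:
            raise InvalidInputError("LJ6_12 vectors have 3 entries")
        lj = LJParams(epsilon=arr[0], sigma=arr[1], p=12.0)
        return cls(lj=lj, sigma_n=float(arr[2]), model_tag=model_tag)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform box prior: per-parameter lower/upper bounds."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size != len(self.names):
            raise InvalidInputError("bounds must be 1-D and match names")
        if np.any(lo >= hi):
            raise InvalidInputError("lower bounds must be strictly below upper bounds")
        if "p" in self.names and lo[self.names.index("p")] <= 6:
            raise InvalidInputError("the p lower bound must exceed 6")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def log_volume(self) -> float:
        return float(np.sum(np.log(self.widths)))

    def contains(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.all((x >= self.lower) & (x <= self.upper), axis=1)

    def log_pdf(self, x) -> np.ndarray:
        """Batched uniform log-density: -sum(log widths) inside, -inf outside."""
        inside = self.contains(x)
        out = np.where(inside, -self.log_volume, -np.inf)
        return out

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.lower + self.widths * rng.random((n, self.dim))

    def subset(self, names) -> "PriorSpec":
        idx = [self.names.index(n) for n in names]
        return PriorSpec(tuple(names), self.lower[idx], self.upper[idx])


def default_prior(model_tag: str) -> PriorSpec:
    """The wide uniform boxes used throughout the calibrations.

    LJ 6-12: (epsilon, sigma, sigma_n) in [0.05, 3] x [3, 4] x [1e-6, 1].
    LJ 6-p:  (epsilon, sigma, p, sigma_n) in
             [0.05, 10] x [3, 4] x [6.01, 15] x [1e-6, 1].
    """
    if model_tag == MODEL_LJ6_12:
        return PriorSpec(
            PARAM_NAMES[MODEL_LJ6_12],
            np.array([0.05, 3.0, 1e-6]),
            np.array([3.0, 4.0, 1.0]),
        )
    if model_tag == MODEL_LJ6_P:
        return PriorSpec(
            PARAM_NAMES[MODEL_LJ6_P],
            np.array([0.05, 3.0, 6.01, 1e-6]),
            np.array([10.0, 4.0, 15.0, 1.0]),
        )
    raise InvalidInputError(f"unknown model_tag {model_tag!r}")


def physical_prior(spec: PriorSpec) -> PriorSpec:
    """The prior box restricted to the physical parameters (sigma_n dropped)."""
    return spec.subset([n for n in spec.names if n != "sigma_n"])


def log_likelihood(dataset, model_curve, sigma_n: float) -> float:
    """Gaussian log-likelihood of a dataset given a model curve.

    ``dataset`` may be a :class:`Dataset` or a plain array of observed values.
    """
    d = dataset.values if isinstance(dataset, Dataset) else np.asarray(dataset, float)
    f = np.asarray(model_curve, dtype=float)
    if d.shape != f.shape:
        raise InvalidInputError(f"curve length mismatch: {d.shape} vs {f.shape}")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
        raise InvalidInputError("data and model curves must be finite")
    if not sigma_n > 0:
        raise InvalidInputError(f"sigma_n must be > 0, got {sigma_n}")
    n = d.size
    sse = float(np.sum((d - f) ** 2))
    return -0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma_n)) - sse / (2.0 * sigma_n ** 2)


def gaussian_log_likelihood_batch(data, curves, sigma_n) -> np.ndarray:
    """Vectorized Gaussian log-likelihood: curves (n, m), sigma_n (n,) -> (n,)."""
    d = np.asarray(data, dtype=float)[None, :]
    sse = np.sum((d - curves) ** 2, axis=1)
    sigma_n = np.asarray(sigma_n, dtype=float)
    n = d.size
    return -0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma_n)) - sse / (2.0 * sigma_n ** 2)


# -- conditional prior families for the hierarchical layer -------------------

class ConditionalPriorFamily:
    """Family of conditional priors p(theta_phys | psi) over a base box.

    Implementations provide ``psi_names``, an admissibility check, a
    hyperprior box for psi, and batched log-densities.  Densities integrate
    to 1 over the base box for every admissible psi.
    """

    name: str = "abstract"

    def __init__(self, base: PriorSpec):
        self.base = base  # physical-parameter box

    @property
    def dim(self) -> int:
        return self.base.dim

    @property
    def psi_names(self) -> tuple[str, ...]:
        raise NotImplementedError

    def admissible(self, psi) -> bool:
        raise NotImplementedError

    def psi_prior(self) -> PriorSpec:
        """Uniform hyperprior box over psi."""
        raise NotImplementedError

    def psi_log_prior(self, psis) -> np.ndarray:
        """Hyperprior log-density, -inf where psi is inadmissible."""
        box = self.psi_prior()
        lp = box.log_pdf(psis)
        psis2 = np.atleast_2d(np.asarray(psis, dtype=float))
        ok = np.array([self._admissible_row(row) for row in psis2])
        return np.where(ok, lp, -np.inf)

    def _admissible_row(self, psi) -> bool:
        return self.admissible(psi)

    def log_pdf(self, theta, psi) -> np.ndarray:
        """log p(theta | psi) for theta (k, d) and a single psi -> (k,)."""
        out = self.log_pdf_batch(theta, np.atleast_2d(np.asarray(psi, float)))
        return out[0]

    def log_pdf_batch(self, theta, psis) -> np.ndarray:
        """log p(theta | psi) for theta (k, d) and psis (m, n_psi) -> (m, k)."""
        raise NotImplementedError


class UniformBoxFamily(ConditionalPriorFamily):
    """psi = (lo_1..d, hi_1..d): a movable uniform sub-box of the base box."""

    name = "uniform_box"

    @property
    def psi_names(self):
        return tuple(f"lo_{n}" for n in self.base.names) + tuple(
            f"hi_{n}" for n in self.base.names
        )

    def admissible(self, psi) -> bool:
        psi = np.asarray(psi, dtype=float)
        d = self.dim
        lo, hi = psi[:d], psi[d:]
        return bool(
            np.all(lo < hi)
            and np.all(lo >= self.base.lower - 1e-12)
            and np.all(hi <= self.base.upper + 1e-12)
        )

    def psi_prior(self) -> PriorSpec:
        lo = np.concatenate([self.base.lower, self.base.lower])
        hi = np.concatenate([self.base.upper, self.base.upper])
        return PriorSpec(self.psi_names, lo, hi)

    def base_psi(self) -> np.ndarray:
        """The psi vector that reproduces the base box exactly."""
        return np.concatenate([self.base.lower, self.base.upper])

    def log_pdf_batch(self, theta, psis):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))  # (k, d)
        psis = np.atleast_2d(np.asarray(psis, dtype=float))  # (m, 2d)
        d = self.dim
        lo = psis[:, None, :d]
        hi = psis[:, None, d:]
        widths = hi - lo  # (m, 1, d)
        valid = np.all(widths[:, 0, :] > 0, axis=1)  # (m,)
        inside = np.all((theta[None, :, :] >= lo) & (theta[None, :, :] <= hi), axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_vol = np.sum(np.log(np.where(widths > 0, widths, np.nan)), axis=2)
        out = np.where(inside, -log_vol, -np.inf)
        out[~valid, :] = -np.inf
        return out


class TruncatedNormalFamily(ConditionalPriorFamily):
    """psi = (loc_1..d, scale_1..d): independent normals truncated to the box.

    Each factor is a normal N(loc_i, scale_i**2) renormalized over
    [lower_i, upper_i].  Large scales recover the uniform box; small scales
    concentrate mass, which is what lets a weakly informed dataset borrow
    strength from the others.
    """

    name = "independent_truncated_normal"

    #: Hyperprior scale bounds, as fractions of the base box width.
    SCALE_LO_FRAC = 1e-3
    SCALE_HI_FRAC = 1.0

    @property
    def psi_names(self):
        return tuple(f"loc_{n}" for n in self.base.names) + tuple(
            f"scale_{n}" for n in self.base.names
        )

    def admissible(self, psi) -> bool:
        psi = np.asarray(psi, dtype=float)
        d = self.dim
        loc, scale = psi[:d], psi[d:]
        return bool(
            np.all(scale > 0)
            and np.all(loc >= self.base.lower - 1e-12)
            and np.all(loc <= self.base.upper + 1e-12)
        )

    def psi_prior(self) -> PriorSpec:
        w = self.base.widths
        lo = np.concatenate([self.base.lower, self.SCALE_LO_FRAC * w])
        hi = np.concatenate([self.base.upper, self.SCALE_HI_FRAC * w])
        return PriorSpec(self.psi_names, lo, hi)

    def log_pdf_batch(self, theta, psis):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))  # (k, d)
        psis = np.atleast_2d(np.asarray(psis, dtype=float))  # (m, 2d)
        d = self.dim
        loc = psis[:, None, :d]  # (m, 1, d)
        scale = psis[:, None, d:]
        if np.any(scale <= 0):
            raise InvalidInputError("truncated-normal scales must be > 0")
        z = (theta[None, :, :] - loc) / scale
        a = (self.base.lower - loc) / scale
        b = (self.base.upper - loc) / scale
        mass = ndtr(b) - ndtr(a)  # (m, 1, d)
        mass = np.maximum(mass, 1e-300)
        logpdf = (
            -0.5 * z ** 2
            - 0.5 * _LOG_2PI
            - np.log(scale)
            - np.log(mass)
        )
        inside = np.all(
            (theta[None, :, :] >= self.base.lower) & (theta[None, :, :] <= self.base.upper),
            axis=2,
        )
        out = np.sum(logpdf, axis=2)
        return np.where(inside, out, -np.inf)


_FAMILIES = {
    UniformBoxFamily.name: UniformBoxFamily,
    TruncatedNormalFamily.name: TruncatedNormalFamily,
}


def get_family(name: str, base: PriorSpec) -> ConditionalPriorFamily:
    """Construct a conditional prior family over a physical base box by name."""
    if name not in _FAMILIES:
        raise InvalidInputError(f"unknown family {name!r}; options: {sorted(_FAMILIES)}")
    return _FAMILIES[name](base)


def conditional_log_prior(theta, psi, family: ConditionalPriorFamily) -> np.ndarray:
    """log p(theta | psi) under a family; errors on inadmissible psi."""
    if not family.admissible(psi):
        raise InvalidInputError(f"inadmissible psi for family {family.name}: {psi}")
    return family.log_pdf(theta, psi)
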