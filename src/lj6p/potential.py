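"""Generalized Lennard-Jones 6-p pair potential.

The pair energy is

    V(r; eps, sigma, p) = 4*eps * ((sigma/r)**p - (sigma/r)**6),

with ``eps`` the well-depth scale (kcal/mol), ``sigma`` the zero crossing
(Angstrom) and ``p > 6`` the repulsion exponent; ``p = 12`` recovers the
classical 6-12 potential.  The attractive ``r**-6`` term models dispersion
forces; the repulsive exponent is treated as a continuous, inferable
parameter.  Simulations conventionally truncate the potential at a cutoff
``r_c = 3*sigma``; truncation here is a hard set-to-zero with no energy shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

#: Boltzmann constant in kcal/(mol K), the package's working unit system
#: (energies in kcal/mol, distances in Angstrom, temperatures in K).
K_B = 0.0019872041

#: Cutoff radius in units of sigma for the truncated potential.
CUTOFF_FACTOR = 3.0


@dataclass(frozen=True)
class LJParams:
    """Physical parameters of the LJ 6-p potential.

    Attributes
    ----------
    epsilon : float
        Well-depth scale in kcal/mol, > 0.
    sigma : float
        Zero-crossing distance in Angstrom, > 0.  ``V(sigma) == 0`` exactly
        for any ``p``.
    p : float
        Repulsion exponent, dimensionless, > 6.  Continuous; 12 is classical.
    """

    epsilon: float
    sigma: float
    p: float = 12.0

    def __post_init__(self):
        for name in ("epsilon", "sigma", "p"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
        if self.epsilon <= 0:
            raise InvalidInputError(f"epsilon must be > 0, got {self.epsilon}")
        if self.sigma <= 0:
            raise InvalidInputError(f"sigma must be > 0, got {self.sigma}")
        if self.p <= 6:
            raise InvalidInputError(f"p must be > 6, got {self.p}")

    @property
    def cutoff(self) -> float:
        """Truncation radius ``3*sigma`` in Angstrom."""
        return CUTOFF_FACTOR * self.sigma


def lj_energy(r, params: LJParams, truncated: bool = False):
    """Pair energy at separation(s) ``r`` (Angstrom), in kcal/mol.

    Parameters
    ----------
    r : float or array_like
        Separation(s), strictly positive.
    params : LJParams
    truncated : bool
        If True, energies at ``r > 3*sigma`` are exactly 0 (plain truncation,
        no shift).

    Returns
    -------
    float or ndarray matching the shape of ``r``.
    """
    r_arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r_arr)) or np.any(r_arr <= 0):
        raise InvalidInputError("separations must be finite and > 0")
    sr = params.sigma / r_arr
    e = 4.0 * params.epsilon * (sr ** params.p - sr ** 6)
    if truncated:
        e = np.where(r_arr > params.cutoff, 0.0, e)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(e)
    return e


def lj_well(params: LJParams) -> tuple[float, float]:
    """Analytic location and depth of the potential minimum.

    Setting dV/dr = 0 gives ``r_min = (p/6)**(1/(p-6)) * sigma``; the depth is
    the (negative) energy there.  As ``p -> 6+`` the minimum drifts out to
    ``exp(1/6)*sigma`` and the well becomes arbitrarily shallow; at ``p = 12``
    the classical ``r_min = 2**(1/6)*sigma`` with depth ``-epsilon`` is
    recovered.

    Returns
    -------
    (r_min, depth) : tuple of float
        Minimum location (Angstrom) and well depth (kcal/mol, < 0).
    """
    p = params.p
    r_min = (p / 6.0) ** (1.0 / (p - 6.0)) * params.sigma
    depth = lj_energy(r_min, params)
    return r_min, float(depth)
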