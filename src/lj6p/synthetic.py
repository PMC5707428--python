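"""Synthetic datasets with the exact statistical structure the model assumes.

Each dataset is a noiseless forward-model curve from a known ground-truth
parameter vector plus i.i.d. Gaussian perturbations of scale ``sigma_n`` —
precisely the noise model of the Gaussian likelihood, so recovery tests are
well-posed.  Ground truths for the presets are the published posterior
values for argon, re-used as generators: this anchors the magnitudes of
every fixture to the real calibration problem without claiming to
reproduce data-dependent posteriors.

Grids: dimer scans cover 0.9*sigma to 2.5*sigma over 40 points (repulsive
wall, well and attractive tail); RDF curves cover 2.5-12 Angstrom over 100
bins, mirroring the standard RDF discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InvalidInputError
from .forward_models import Condition, Dataset, builtin_model
from .likelihood import (
    MODEL_LJ6_12,
    MODEL_LJ6_P,
    ParamVector,
    default_prior,
)
from .potential import LJParams

#: Number of grid points for dimer binding-energy scans.
DIMER_GRID_POINTS = 40

#: Dimer grid endpoints in units of the truth sigma.
DIMER_GRID_SPAN = (0.9, 2.5)

#: RDF grid: 100 bins over 2.5-12 Angstrom.
RDF_GRID = (2.5, 12.0, 100)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset: truth, grid, noise and seed."""

    name: str
    truth: ParamVector
    kind: str  # rdf | dimer_energy
    condition: Condition
    r_min: float
    r_max: float
    n_points: int
    noise_sigma: float
    seed: int

    def __post_init__(self):
        if self.kind not in ("rdf", "dimer_energy"):
            raise InvalidInputError(f"unknown kind {self.kind!r}")
        if self.n_points < 2:
            raise InvalidInputError("n_points must be >= 2")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")
        if not 0 < self.r_min < self.r_max:
            raise InvalidInputError("need 0 < r_min < r_max")
        box = default_prior(self.truth.model_tag)
        if not bool(box.contains(self.truth.to_array())[0]):
            raise InvalidInputError(
                f"truth {self.truth} lies outside the {self.truth.model_tag} prior box"
            )

    @property
    def r_grid(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_max, self.n_points)


def generate(spec: SyntheticSpec) -> Dataset:
    """Noiseless forward curve from the truth plus i.i.d. N(0, sigma_n^2) noise.

    Deterministic given ``spec.seed``; with ``noise_sigma == 0`` the dataset
    equals the forward-model curve exactly.
    """
    model = builtin_model(spec.kind)
    clean = model.evaluate(spec.truth.lj, spec.condition, spec.r_grid)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=clean.shape) if spec.noise_sigma > 0 else 0.0
    return Dataset(
        kind=spec.kind,
        condition=spec.condition,
        r_grid=spec.r_grid,
        values=clean + noise,
    )


def _dimer_spec(name, truth: ParamVector, noise, seed, label="Q") -> SyntheticSpec:
    s = truth.lj.sigma
    return SyntheticSpec(
        name=name,
        truth=truth,
        kind="dimer_energy",
        condition=Condition(label=label),
        r_min=DIMER_GRID_SPAN[0] * s,
        r_max=DIMER_GRID_SPAN[1] * s,
        n_points=DIMER_GRID_POINTS,
        noise_sigma=noise,
        seed=seed,
    )


def argon_presets() -> dict[str, SyntheticSpec]:
    """Named, seeded generator specs anchored to the published argon posteriors.

    ``dimer_Q`` uses the gas-phase LJ 6-p posterior (epsilon = 0.252,
    sigma = 3.370, p = 12.703, sigma_n = 0.006); the RDF presets use the
    hierarchical liquid/vapor LJ 6-p posteriors (p near 6.3-6.6, sigma near
    3.1-3.45) at their six (T, P) conditions, with the posterior sigma_n as
    the generating noise.
    """
    presets: dict[str, SyntheticSpec] = {}
    dimer_truth = ParamVector(
        lj=LJParams(epsilon=0.252, sigma=3.370, p=12.703),
        sigma_n=0.006,
        model_tag=MODEL_LJ6_P,
    )
    presets["dimer_Q"] = _dimer_spec("dimer_Q", dimer_truth, noise=0.006, seed=2017)

    rdf_rows = {
        # label: (epsilon, sigma, p, sigma_n, T [K], P [atm])
        "rdf_L1": (4.561, 3.454, 6.302, 0.422, 84.4, 0.8),
        "rdf_L2": (2.081, 3.387, 6.565, 0.211, 91.8, 1.8),
        "rdf_L3": (2.506, 3.345, 6.324, 0.093, 126.7, 18.3),
        "rdf_L4": (2.588, 3.403, 6.339, 0.082, 144.1, 37.7),
        "rdf_L5": (2.055, 3.252, 6.364, 0.183, 149.3, 46.8),
        "rdf_V": (1.371, 3.129, 6.422, 0.111, 149.3, 43.8),
    }
    r_min, r_max, n_bins = RDF_GRID
    for i, (name, (eps, sig, p, sn, temp, pres)) in enumerate(rdf_rows.items()):
        truth = ParamVector(
            lj=LJParams(epsilon=eps, sigma=sig, p=p),
            sigma_n=sn,
            model_tag=MODEL_LJ6_P,
        )
        presets[name] = SyntheticSpec(
            name=name,
            truth=truth,
            kind="rdf",
            condition=Condition(label=name.split("_")[1], temperature=temp, pressure=pres),
            r_min=r_min,
            r_max=r_max,
            n_points=n_bins,
            noise_sigma=sn,
            seed=3000 + i,
        )
    return presets


#: Noise scale for the model-selection fixtures, kcal/mol.  Chosen once as
#: the magnitude of the RMS residual of the best LJ 6-12 fit to the
#: noiseless p = 6.5 dimer curve (measured at ~0.01 with least squares), so
#: the model-misfit signal and the noise floor are comparable.
MODEL_SELECTION_NOISE = 0.01


def model_selection_presets() -> dict[str, SyntheticSpec]:
    """Dimer fixtures for the evidence-direction experiments.

    ``dimer_p12``: truth generated by the classical 6-12 potential
    (literature-style epsilon = 0.2824, sigma = 3.3605), so the 3-parameter
    model should win by parsimony.  ``dimer_p65``: truth p = 6.5 with the
    same noise, so only the 4-parameter model can fit.
    """
    p12_truth = ParamVector(
        lj=LJParams(epsilon=0.2824, sigma=3.3605, p=12.0),
        sigma_n=MODEL_SELECTION_NOISE,
        model_tag=MODEL_LJ6_12,
    )
    p65_truth = ParamVector(
        lj=LJParams(epsilon=0.30, sigma=3.40, p=6.5),
        sigma_n=MODEL_SELECTION_NOISE,
        model_tag=MODEL_LJ6_P,
    )
    return {
        "dimer_p12": _dimer_spec("dimer_p12", p12_truth, MODEL_SELECTION_NOISE, seed=4100),
        "dimer_p65": _dimer_spec("dimer_p65", p65_truth, MODEL_SELECTION_NOISE, seed=4200),
    }


def hb_shrinkage_presets(weak_factor: float = 5.0) -> list[SyntheticSpec]:
    """Three informative + one weak (``weak_factor`` x noise) dimer datasets.

    All four share the gas-phase ground truth; only the noise scale of the
    last differs, which is the configuration in which hierarchical pooling
    should visibly shrink the weak dataset's epsilon uncertainty.
    """
    base = argon_presets()["dimer_Q"]
    specs = []
    for i in range(3):
        specs.append(replace(base, name=f"dimer_info_{i}", seed=5000 + i))
    weak_noise = base.noise_sigma * weak_factor
    weak_truth = replace(base.truth, sigma_n=weak_noise)
    specs.append(
        replace(base, name="dimer_weak", truth=weak_truth,
                noise_sigma=weak_noise, seed=5900)
    )
    return specs
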