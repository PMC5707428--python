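"""Forward models mapping LJ parameters to observable curves.

Two closed-form models are built in:

* ``dimer_energy_model`` — the pair potential itself evaluated on an r-grid,
  the observable probed by quantum dimer binding-energy scans.  Untruncated:
  a quantum scan resolves the attractive tail beyond any simulation cutoff
  and a hard zero there would be unphysical for curve fitting.
* ``dilute_rdf_model`` — a low-density radial distribution function
  ``g(r) = exp(-V_trunc(r)/(k_B T))``, exact in the dilute-gas limit.  This
  is an openly declared surrogate for an MD-computed liquid RDF: it
  preserves the parameter sensitivities that drive the inference (sigma sets
  the peak location, epsilon its height) while being evaluable in
  microseconds.  It uses the truncated potential, mirroring the simulation
  convention, so g(r) == 1 exactly beyond the cutoff.

Production MD engines are reached only through :func:`register_external_engine`,
which wraps a shell command template; this package never implements molecular
dynamics itself.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EngineError, InvalidInputError
from .potential import CUTOFF_FACTOR, K_B, LJParams, lj_energy

_KINDS = ("rdf", "dimer_energy")

#: Default bound on |V/(k_B T)| before exponentiation in the dilute RDF.
EXP_CLIP = 50.0


@dataclass(frozen=True)
class Condition:
    """Thermodynamic condition labelling a dataset.

    ``temperature`` (K) and ``pressure`` (atm) may be absent for dimer data,
    which is a property of the isolated pair rather than a bulk state.
    """

    label: str
    temperature: float | None = None
    pressure: float | None = None

    def __post_init__(self):
        if self.temperature is not None and not self.temperature > 0:
            raise InvalidInputError(
                f"temperature must be > 0 when present, got {self.temperature}"
            )


@dataclass(frozen=True)
class Dataset:
    """One observable curve: kind, condition, r-grid and observed values."""

    kind: str
    condition: Condition
    r_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidInputError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        r = np.asarray(self.r_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if r.ndim != 1 or v.ndim != 1 or r.size != v.size:
            raise InvalidInputError("r_grid and values must be equal-length 1-D arrays")
        if r.size < 2:
            raise InvalidInputError("need at least 2 points")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise InvalidInputError("r_grid must be positive and strictly increasing")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(v))):
            raise InvalidInputError("r_grid and values must be finite")
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.r_grid.size


def dimer_energy_model(params: LJParams, r_grid) -> np.ndarray:
    """Binding-energy curve E(r) in kcal/mol: the untruncated pair potential."""
    return np.atleast_1d(lj_energy(r_grid, params, truncated=False))


def dilute_rdf_model(
    params: LJParams, condition: Condition, r_grid, exp_clip: float = EXP_CLIP
) -> np.ndarray:
    """Dilute-gas g(r) = exp(-V_trunc(r) / (k_B T)), dimensionless.

    The exponent is clipped to ``[-exp_clip, exp_clip]`` so that deep-well
    parameter proposals stay finite and ordered rather than overflowing.
    """
    if condition.temperature is None:
        raise InvalidInputError("dilute_rdf_model requires a temperature")
    v = lj_energy(r_grid, params, truncated=True)
    arg = np.clip(-np.atleast_1d(v) / (K_B * condition.temperature), -exp_clip, exp_clip)
    return np.exp(arg)


# -- batched curve evaluation (one row per parameter vector) -----------------

def dimer_energy_curves(eps, sig, p, r_grid) -> np.ndarray:
    """Vectorized dimer curves: (n,) parameter arrays -> (n, m) energies."""
    r = np.asarray(r_grid, dtype=float)[None, :]
    sr = np.asarray(sig, dtype=float)[:, None] / r
    return 4.0 * np.asarray(eps, dtype=float)[:, None] * (
        sr ** np.asarray(p, dtype=float)[:, None] - sr ** 6
    )


def dilute_rdf_curves(eps, sig, p, temperature, r_grid, exp_clip: float = EXP_CLIP):
    """Vectorized dilute-gas g(r): (n,) parameter arrays -> (n, m) curves."""
    r = np.asarray(r_grid, dtype=float)[None, :]
    sig = np.asarray(sig, dtype=float)[:, None]
    sr = sig / r
    v = 4.0 * np.asarray(eps, dtype=float)[:, None] * (
        sr ** np.asarray(p, dtype=float)[:, None] - sr ** 6
    )
    v = np.where(r > CUTOFF_FACTOR * sig, 0.0, v)
    return np.exp(np.clip(-v / (K_B * temperature), -exp_clip, exp_clip))


# -- forward-model objects ----------------------------------------------------

class ForwardModel:
    """Contract: a deterministic map (theta, condition, r_grid) -> curve.

    ``evaluate`` must return a curve of the same length as ``r_grid`` and be
    pure (bit-identical on repeated calls with identical inputs).
    """

    descriptor: str = "abstract"

    def evaluate(self, params: LJParams, condition: Condition, r_grid) -> np.ndarray:
        raise NotImplementedError


class DimerEnergyModel(ForwardModel):
    descriptor = "closed-form LJ 6-p dimer binding energy"

    def evaluate(self, params, condition, r_grid):
        return dimer_energy_model(params, r_grid)


class DiluteGasRDFModel(ForwardModel):
    descriptor = "dilute-gas RDF stand-in exp(-V_trunc/kT)"

    def evaluate(self, params, condition, r_grid):
        return dilute_rdf_model(params, condition, r_grid)


def builtin_model(kind: str) -> ForwardModel:
    """Closed-form forward model for a dataset kind."""
    if kind == "dimer_energy":
        return DimerEnergyModel()
    if kind == "rdf":
        return DiluteGasRDFModel()
    raise InvalidInputError(f"no builtin forward model for kind {kind!r}")


def _parse_two_column(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for i, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.replace(",", " ").split()
        if len(parts) != 2:
            raise EngineError(f"engine output line {i}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise EngineError(f"engine output line {i}: non-numeric value") from exc
    if not rows:
        raise EngineError("engine produced no parseable output rows")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


@dataclass
class ExternalEngine(ForwardModel):
    """Adapter shelling out to an external simulation engine per evaluation.

    The command template carries placeholders ``{epsilon} {sigma} {p}
    {temperature} {pressure}``; the engine must write a two-column
    whitespace- or comma-delimited r/value table to stdout whose length
    matches the requested grid.

    The documented reference protocol for a production MD backend is: 666
    atoms under periodic boundaries, NPT equilibration of 5e6 steps of 2 fs,
    NVE production of 1e5 steps, RDF accumulated over 100 bins.  That
    protocol lives entirely in the engine; this adapter only transports
    parameters out and curves back.
    """

    command: str
    name: str = "external-engine"
    parser: object = None  # callable(text) -> (r, values); default 2-column

    def __post_init__(self):
        self.descriptor = f"external engine: {self.name}"

    def evaluate(self, params, condition, r_grid):
        r_grid = np.asarray(r_grid, dtype=float)
        cmd = self.command.format(
            epsilon=params.epsilon,
            sigma=params.sigma,
            p=params.p,
            temperature="" if condition.temperature is None else condition.temperature,
            pressure="" if condition.pressure is None else condition.pressure,
        )
        argv = shlex.split(cmd)
        try:
            proc = subprocess.run(argv, capture_output=True, text=True, check=False)
        except (FileNotFoundError, PermissionError) as exc:
            raise EngineError(f"engine executable not runnable: {argv[0]!r}: {exc}") from exc
        if proc.returncode != 0:
            raise EngineError(
                f"engine exited with status {proc.returncode}; stderr: {proc.stderr.strip()!r}"
            )
        parse = self.parser if self.parser is not None else _parse_two_column
        _, values = parse(proc.stdout)
        values = np.asarray(values, dtype=float)
        if values.size != r_grid.size:
            raise EngineError(
                f"engine curve length mismatch: expected {r_grid.size}, got {values.size}"
            )
        return values


def register_external_engine(descriptor: dict) -> ForwardModel:
    """Build a :class:`ForwardModel` from an engine descriptor.

    ``descriptor`` must contain a ``command`` template; optional keys are
    ``name`` and ``parser`` (a callable mapping raw output text to an
    ``(r, values)`` pair).  The executable named by the template's first
    token must exist on PATH or as a file.
    """
    if not isinstance(descriptor, dict) or "command" not in descriptor:
        raise EngineError("engine descriptor must be a dict with a 'command' template")
    head = shlex.split(descriptor["command"])[0]
    if shutil.which(head) is None:
        raise EngineError(f"engine executable not found: {head!r}")
    return ExternalEngine(
        command=descriptor["command"],
        name=descriptor.get("name", "external-engine"),
        parser=descriptor.get("parser"),
    )
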