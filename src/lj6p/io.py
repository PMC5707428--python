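"""Curve-table and run-configuration I/O.

Observable curves travel as two-column plain-text tables (whitespace- or
comma-delimited, ``#`` comments ignored) with a JSON sidecar
(``<path>.json``) carrying the metadata a bare table cannot: the dataset
kind, the condition label, temperature and pressure, and — for synthetic
data — the generating truth and seed, so fixtures are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParseError
from .forward_models import Condition, Dataset


def read_curve_table(path, kind: str | None = None,
                     condition: Condition | None = None) -> Dataset:
    """Parse a two-column r/value table into a :class:`Dataset`.

    Metadata resolution order: explicit ``kind``/``condition`` arguments,
    then the ``<path>.json`` sidecar, then an error.  Malformed rows and
    non-increasing r raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric row {s!r}") from None
            lines.append(lineno)
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, got {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    r, v = arr[:, 0], arr[:, 1]
    bad = np.flatnonzero(np.diff(r) <= 0)
    if bad.size:
        raise ParseError(
            f"{path}:{lines[bad[0] + 1]}: r values must be strictly increasing"
        )

    sidecar = {}
    sc_path = path.with_name(path.name + ".json")
    if sc_path.exists():
        with open(sc_path) as fh:
            sidecar = json.load(fh)
    if kind is None:
        kind = sidecar.get("kind")
    if kind is None:
        raise ParseError(f"{path}: dataset kind not given and no sidecar found")
    if condition is None:
        condition = Condition(
            label=sidecar.get("label", path.stem),
            temperature=sidecar.get("temperature"),
            pressure=sidecar.get("pressure"),
        )
    return Dataset(kind=kind, condition=condition, r_grid=r, values=v)


def write_curve_table(dataset: Dataset, path, extra_sidecar: dict | None = None) -> None:
    """Write a dataset as a two-column table plus its JSON sidecar.

    Values are written with full float precision so write-then-read
    round-trips exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {dataset.kind} curve, condition {dataset.condition.label}\n")
        fh.write("# r  value\n")
        for r, v in zip(dataset.r_grid, dataset.values):
            fh.write(f"{float(r)!r} {float(v)!r}\n")  # shortest exact repr
    sidecar = {
        "kind": dataset.kind,
        "label": dataset.condition.label,
        "temperature": dataset.condition.temperature,
        "pressure": dataset.condition.pressure,
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


@dataclass
class RunConfig:
    """Structured configuration of one CLI run (JSON-serializable)."""

    model_tag: str = "LJ6_p"
    n_samples: int | None = None
    seed: int = 0
    family: str = "independent_truncated_normal"
    surrogate: bool = False
    dataset_paths: list[str] = field(default_factory=list)
    output_dir: str = "."

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: v for k, v in payload.items() if k in cls.__dataclass_fields__})
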