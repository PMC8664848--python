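"""Regulatory standards tables.

A :class:`StandardsTable` holds, for every measured water property, the
admissible range prescribed by a sanitary regulation (the packaged default
reproduces the Russian SanPiN 1.2.3685-21 drinking-water limits).  These
bounds drive two downstream computations: the upper limits of the bounded
warping transform, and the integration rectangle of the probabilistic
quality index.

Conventions
-----------
* A missing lower bound on a regulated parameter means "at most the upper
  limit"; since all concentrations are non-negative the effective interval
  is ``(0, upper)``.
* A parameter with neither bound is *unregulated* and is excluded from the
  quality index entirely.
* ``hard_domain`` is the physical support of the quantity (e.g. pH lies in
  [0, 14]); it is used by the warp, never by the index.
* Units are kept verbatim from the source regulation; no conversion is done.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

__all__ = [
    "ParameterSpec",
    "StandardsTable",
    "load_standards",
    "default_standards",
    "effective_bounds",
    "EXCLUDED",
]

#: Sentinel returned by :func:`effective_bounds` for unregulated parameters.
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ParameterSpec:
    """Admissible range of a single water property."""

    name: str
    unit: str
    normative_lower: Optional[float] = None
    normative_upper: Optional[float] = None
    hard_domain: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        lo, up = self.normative_lower, self.normative_upper
        if lo is not None and up is not None and not lo < up:
            raise ValueError(
                f"parameter {self.name!r}: normative lower bound {lo} must be "
                f"strictly below upper bound {up}"
            )
        if lo is not None and up is None:
            raise ValueError(
                f"parameter {self.name!r}: a lower bound without an upper "
                "bound is not a supported standard form"
            )
        if self.hard_domain is not None:
            hlo, hup = self.hard_domain
            if not hlo < hup:
                raise ValueError(
                    f"parameter {self.name!r}: degenerate hard domain {self.hard_domain}"
                )
            for b in (lo, up):
                if b is not None and not (hlo <= b <= hup):
                    raise ValueError(
                        f"parameter {self.name!r}: normative bound {b} outside "
                        f"hard domain {self.hard_domain}"
                    )

    @property
    def regulated(self) -> bool:
        return self.normative_upper is not None or self.normative_lower is not None


class StandardsTable:
    """Ordered collection of :class:`ParameterSpec`.

    The order of the specs defines the canonical column order of every
    N×M measurement matrix downstream.
    """

    def __init__(self, specs: Sequence[ParameterSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dup}")
        self.specs: Tuple[ParameterSpec, ...] = tuple(specs)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def regulated_names(self) -> Tuple[str, ...]:
        return tuple(s.name for s in self.specs if s.regulated)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __getitem__(self, name: str) -> ParameterSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    def subset(self, names: Iterable[str]) -> "StandardsTable":
        """Restrict to (and reorder by) the given parameter names."""
        return StandardsTable([self[n] for n in names])


def _cell_to_float(value, row_label: str, column: str) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    if isinstance(value, str):
        value = value.strip()
        # em/en dashes and empty cells mean "no bound"
        if value in ("", "-", "–", "—", "null", "None"):
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row_label!r}: non-numeric value {value!r} in column {column!r}"
        ) from None


_REQUIRED = ("name", "unit", "lower", "upper")


def _table_from_records(records: Sequence[Mapping]) -> StandardsTable:
    specs = []
    for rec in records:
        missing = [c for c in _REQUIRED if c not in rec]
        if missing:
            raise ValueError(f"standards record {rec!r}: missing columns {missing}")
        name = str(rec["name"]).strip()
        lo = _cell_to_float(rec.get("lower"), name, "lower")
        up = _cell_to_float(rec.get("upper"), name, "upper")
        hlo = _cell_to_float(rec.get("hard_lower"), name, "hard_lower")
        hup = _cell_to_float(rec.get("hard_upper"), name, "hard_upper")
        hard = (hlo, hup) if hlo is not None and hup is not None else None
        specs.append(
            ParameterSpec(
                name=name,
                unit=str(rec["unit"]).strip(),
                normative_lower=lo,
                normative_upper=up,
                hard_domain=hard,
            )
        )
    return StandardsTable(specs)


def load_standards(
    path: Union[str, Path],
    format: Optional[str] = None,
    overrides: Optional[Mapping[str, Tuple[Optional[float], Optional[float]]]] = None,
) -> StandardsTable:
    """Load a standards table from CSV or YAML.

    Parameters
    ----------
    path:
        CSV file with header ``name,unit,lower,upper[,hard_lower,hard_upper]``
        or a YAML list of mappings with the same keys.  Empty cells or a
        dash mean "no bound".
    format:
        ``"csv"`` or ``"yaml"``; inferred from the suffix when omitted.
    overrides:
        Optional ``{name: (lower, upper)}`` replacing the normative bounds of
        selected parameters, e.g. ``{"Fe": (None, 1.0)}`` for the permissive
        reading of an ambiguous printed range.
    """
    path = Path(path)
    if format is None:
        format = "yaml" if path.suffix.lower() in (".yml", ".yaml") else "csv"
    if format == "csv":
        frame = pd.read_csv(path, dtype=str)
        missing = [c for c in _REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"standards file {path}: missing columns {missing}")
        records = frame.to_dict("records")
    elif format == "yaml":
        with open(path) as fh:
            records = yaml.safe_load(fh)
        if not isinstance(records, list):
            raise ValueError(f"standards file {path}: expected a YAML list of mappings")
    else:
        raise ValueError(f"unknown standards format {format!r}")
    table = _table_from_records(records)
    if overrides:
        table = _apply_overrides(table, overrides)
    return table


def _apply_overrides(table, overrides) -> StandardsTable:
    specs = []
    for s in table:
        if s.name in overrides:
            lo, up = overrides[s.name]
            s = ParameterSpec(s.name, s.unit, lo, up, s.hard_domain)
        specs.append(s)
    return StandardsTable(specs)


def default_standards(
    overrides: Optional[Mapping[str, Tuple[Optional[float], Optional[float]]]] = None,
) -> StandardsTable:
    """The packaged SanPiN 1.2.3685-21 drinking-water table (21 parameters).

    Fe is stored with the strict upper limit 0.3 mg/L; the printed range in
    the regulation admits a permissive reading of 1 mg/L, available as
    ``overrides={"Fe": (None, 1.0)}``.
    """
    ref = resources.files("psqi_geo.data").joinpath("sanpin_1_2_3685_21.csv")
    with resources.as_file(ref) as p:
        return load_standards(p, format="csv", overrides=overrides)


def effective_bounds(spec: ParameterSpec):
    """Integration interval used by the quality index.

    Two-sided standards return ``(lower, upper)``; one-sided upper limits
    return ``(0, upper)`` (concentrations are non-negative); unregulated
    parameters return :data:`EXCLUDED`.
    """
    if not spec.regulated:
        return EXCLUDED
    lo = spec.normative_lower if spec.normative_lower is not None else 0.0
    return (float(lo), float(spec.normative_upper))
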