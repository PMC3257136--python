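"""Domain types and I/O for paired experimental/calculated NMR chemical shifts.

A :class:`ShiftTable` holds, for one candidate structure, one nucleus and one
level of theory, the per-position experimental shifts (from the recorded
spectrum) alongside the calculated shifts (GIAO isotropic shieldings referenced
against TMS).  Raw shieldings can be converted with :func:`shielding_to_shift`
using the standard convention delta = sigma_ref - sigma.

The reference dataset for the ferulamide heterologous series (candidates O, S
and N — ester, thioester and amide at position 9′ — plus ferulic acid itself)
ships with the package and is returned by :func:`load_builtin_fixtures`.
"""

from __future__ import annotations

import enum
import io
import logging
import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("shiftdiscrim")

__all__ = [
    "Nucleus",
    "ShiftObservation",
    "ShiftTable",
    "TMSReference",
    "DEFAULT_TMS",
    "CandidateSet",
    "FormatError",
    "ValidationError",
    "read_shift_table",
    "write_shift_table",
    "shielding_to_shift",
    "load_builtin_fixtures",
    "builtin_printed_residuals",
    "MIN_OBSERVATIONS",
]

#: Regression denominators use n-2 and n-k-1; four points is the smallest
#: table for which every reported statistic is defined.
MIN_OBSERVATIONS = 4

#: Canonical column names of the delimited-text schema.
SCHEMA_COLUMNS = ("position", "nucleus", "delta_exp", "delta_calc", "candidate", "method")


class FormatError(ValueError):
    """Malformed input file: missing columns or unparseable cells."""


class ValidationError(ValueError):
    """Structurally parseable data violating a domain invariant."""


class Nucleus(enum.Enum):
    H1 = "H1"
    C13 = "C13"

    @classmethod
    def coerce(cls, value: "Nucleus | str") -> "Nucleus":
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper().replace("1H", "H1").replace("13C", "C13")
        try:
            return cls[key]
        except KeyError:
            raise ValidationError(f"unknown nucleus: {value!r}") from None


def _normalize_position(label: str) -> str:
    """Canonicalise a position label: ASCII apostrophes become prime marks,
    internal whitespace is removed (the printed tables use '8′ a')."""
    label = str(label).strip().replace("'", "′").replace("ʹ", "′")
    return "".join(label.split())


@dataclass(frozen=True)
class ShiftObservation:
    """One position of a spectrum: experimental and calculated shift in ppm."""

    position: str
    delta_exp: float
    delta_calc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _normalize_position(self.position))
        if not self.position:
            raise ValidationError("position label must be non-empty")
        for name in ("delta_exp", "delta_calc"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValidationError(f"{name} must be a finite number, got {v!r}")


@dataclass(frozen=True)
class ShiftTable:
    """Paired shifts for one candidate x nucleus x method.

    ``compound`` groups tables describing the same measured spectrum; a
    discrimination set may carry an additional reference compound (measured
    separately) alongside the candidate series.
    """

    nucleus: Nucleus
    candidate: str
    method: str
    observations: tuple[ShiftObservation, ...]
    compound: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleus", Nucleus.coerce(self.nucleus))
        object.__setattr__(self, "observations", tuple(self.observations))
        if len(self.observations) < MIN_OBSERVATIONS:
            raise ValidationError(
                f"need at least {MIN_OBSERVATIONS} observations, got {len(self.observations)}"
            )
        seen: set[str] = set()
        for obs in self.observations:
            if obs.position in seen:
                raise ValidationError(f"duplicate position label {obs.position!r}")
            seen.add(obs.position)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(o.position for o in self.observations)

    @property
    def delta_exp(self) -> tuple[float, ...]:
        return tuple(o.delta_exp for o in self.observations)

    @property
    def delta_calc(self) -> tuple[float, ...]:
        return tuple(o.delta_calc for o in self.observations)

    def observation(self, position: str) -> ShiftObservation:
        key = _normalize_position(position)
        for obs in self.observations:
            if obs.position == key:
                return obs
        raise KeyError(position)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "nucleus": self.nucleus.value,
                "delta_exp": self.delta_exp,
                "delta_calc": self.delta_calc,
                "candidate": self.candidate,
                "method": self.method,
            }
        )


@dataclass(frozen=True)
class TMSReference:
    """Isotropic shieldings (ppm) of the TMS reference nuclei."""

    sigma_ref_H: float = 32.1843
    sigma_ref_C: float = 186.3296

    def __post_init__(self) -> None:
        if self.sigma_ref_H <= 0 or self.sigma_ref_C <= 0:
            raise ValidationError("reference shieldings must be positive")

    def sigma_for(self, nucleus: Nucleus | str) -> float:
        nucleus = Nucleus.coerce(nucleus)
        return self.sigma_ref_H if nucleus is Nucleus.H1 else self.sigma_ref_C


#: Gas-phase TMS shieldings used by the bundled study data.
DEFAULT_TMS = TMSReference()


def shielding_to_shift(
    sigma: float, nucleus: Nucleus | str, ref: TMSReference = DEFAULT_TMS
) -> float:
    """Convert an isotropic shielding constant to a chemical shift,
    delta = sigma_ref - sigma (ppm)."""
    return ref.sigma_for(nucleus) - sigma


Key = tuple[str, Nucleus, str]


@dataclass
class CandidateSet:
    """All shift tables of one discrimination experiment, keyed by
    (candidate, nucleus, method).

    Tables sharing (nucleus, method) describe the same experimental spectrum
    and must therefore agree on position labels and experimental shifts.
    """

    experiment_id: str
    tables: dict[Key, ShiftTable] = field(default_factory=dict)

    def add(self, table: ShiftTable) -> None:
        key = (table.candidate, table.nucleus, table.method)
        if key in self.tables:
            raise ValidationError(f"duplicate table for {key}")
        for other in self.tables.values():
            if (other.compound, other.nucleus, other.method) == (
                table.compound, table.nucleus, table.method
            ):
                if other.positions != table.positions or other.delta_exp != table.delta_exp:
                    raise ValidationError(
                        f"experimental spectrum mismatch between candidates "
                        f"{other.candidate!r} and {table.candidate!r} "
                        f"({table.nucleus.value}, {table.method})"
                    )
        self.tables[key] = table

    def table(self, candidate: str, nucleus: Nucleus | str, method: str) -> ShiftTable:
        return self.tables[(candidate, Nucleus.coerce(nucleus), method)]

    def __iter__(self):
        return iter(self.tables.values())

    def __len__(self) -> int:
        return len(self.tables)

    @property
    def blocks(self) -> list[tuple[Nucleus, str]]:
        """Distinct (nucleus, method) combinations, in insertion order."""
        seen: dict[tuple[Nucleus, str], None] = {}
        for t in self.tables.values():
            seen.setdefault((t.nucleus, t.method), None)
        return list(seen)

    @property
    def candidates(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tables.values():
            seen.setdefault(t.candidate, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "position": ("position", "pos", "label", "atom"),
    "delta_exp": ("delta_exp", "exp", "experimental", "d_exp"),
    "delta_calc": ("delta_calc", "calc", "calculated", "d_calc"),
}


def _read_frame(source) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    return pd.read_csv(io.StringIO(text), sep=sep, dtype=str, skipinitialspace=True)


def _resolve(frame: pd.DataFrame, logical: str) -> str:
    lowered = {c.strip().lower(): c for c in frame.columns}
    for alias in _COLUMN_ALIASES[logical]:
        if alias in lowered:
            return lowered[alias]
    raise FormatError(f"missing required column {logical!r} (have: {list(frame.columns)})")


def _parse_shift(cell, column: str, position: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in ("", "-", "nan", "NA"):
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"non-numeric value {text!r} in column {column!r} at position {position!r}"
        ) from None


def read_shift_table(
    source,
    nucleus: Nucleus | str,
    candidate: str,
    method: str,
) -> ShiftTable:
    """Read one candidate's shift table from a CSV/TSV stream or path.

    The file needs a header naming at least the position, experimental and
    calculated columns.  Rows whose calculated (or experimental) cell is empty
    are excluded pairwise with a logged warning; non-numeric cells are an
    error.  Row order is preserved.
    """
    frame = _read_frame(source)
    pos_col = _resolve(frame, "position")
    exp_col = _resolve(frame, "delta_exp")
    calc_col = _resolve(frame, "delta_calc")

    observations: list[ShiftObservation] = []
    for _, row in frame.iterrows():
        pos = str(row[pos_col]).strip()
        exp = _parse_shift(row[exp_col], exp_col, pos)
        calc = _parse_shift(row[calc_col], calc_col, pos)
        if exp is None or calc is None:
            logger.warning(
                "position %r excluded pairwise: missing %s value",
                pos,
                "experimental" if exp is None else "calculated",
            )
            continue
        observations.append(ShiftObservation(pos, exp, calc))
    return ShiftTable(Nucleus.coerce(nucleus), candidate, method, tuple(observations))


def write_shift_table(table: ShiftTable, target) -> None:
    """Write a table in the canonical long schema (CSV).

    Floats are written in shortest round-tripping form, so read -> write ->
    read reproduces all values exactly.
    """
    table.to_frame().to_csv(target, index=False)


def write_candidate_set(cset: CandidateSet, directory) -> list[str]:
    """Write every table of a set into *directory*, one CSV per table."""
    os.makedirs(directory, exist_ok=True)
    written = []
    for (cand, nuc, meth), table in cset.tables.items():
        safe_meth = meth.replace("/", "_").replace("(", "").replace(")", "").replace(",", "_")
        path = os.path.join(directory, f"{cand}_{nuc.value}_{safe_meth}.csv")
        write_shift_table(table, path)
        written.append(path)
    return written


def read_candidate_set(paths_and_keys: Iterable[tuple[object, str, Nucleus | str, str]],
                       experiment_id: str = "run") -> CandidateSet:
    """Assemble a CandidateSet from (source, candidate, nucleus, method) tuples."""
    cset = CandidateSet(experiment_id)
    for source, candidate, nucleus, method in paths_and_keys:
        cset.add(read_shift_table(source, nucleus, candidate, method))
    return cset


# ---------------------------------------------------------------------------
# Bundled study data
# ---------------------------------------------------------------------------

_FIXTURE_FILES = ("fad_c13.tsv", "fad_h1.tsv", "fa_b3lyp.tsv")


def _fixture_frames() -> list[pd.DataFrame]:
    frames = []
    for name in _FIXTURE_FILES:
        with resources.files("shiftdiscrim.data").joinpath(name).open("r", encoding="utf-8") as fh:
            frames.append(pd.read_csv(fh, sep="\t"))
    return frames


def load_builtin_fixtures() -> CandidateSet:
    """The bundled ferulamide discrimination dataset.

    Returns 14 tables: candidates O/S/N at two levels of theory for both
    nuclei (12 tables; n=18 for carbon, n=12 for proton including the
    diastereotopic 8′a/8′b pair) plus ferulic acid at B3LYP/6-31+G(d,p)
    (n=10 carbon, n=6 proton).  Two cells are reconciled against the tables'
    own residual column; see docs/methods.md.
    """
    cset = CandidateSet("ferulamide-heterologous-series")
    for frame in _fixture_frames():
        for (cand, nuc, meth), grp in frame.groupby(
            ["candidate", "nucleus", "method"], sort=False
        ):
            obs = tuple(
                ShiftObservation(r.position, float(r.delta_exp), float(r.delta_calc))
                for r in grp.itertuples()
            )
            compound = "FA" if cand == "FA" else "FAD"
            cset.add(ShiftTable(Nucleus.coerce(nuc), cand, meth, obs, compound=compound))
    return cset


def builtin_printed_residuals() -> Mapping[tuple[str, Nucleus, str, str], float]:
    """Residual (RS) values as printed in the source tables, keyed by
    (candidate, nucleus, method, position).  Used to audit the fixtures."""
    printed: dict[tuple[str, Nucleus, str, str], float] = {}
    for frame in _fixture_frames():
        for r in frame.itertuples():
            key = (r.candidate, Nucleus.coerce(r.nucleus), r.method,
                   _normalize_position(r.position))
            printed[key] = float(r.rs_printed)
    return printed
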