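"""Comparison of experimental IR absorption bands with harmonic frequencies.

Each band pairs an experimental wavenumber (possibly absent — some modes are
not resolved in the spectrum) with one theoretical value per candidate and
level of theory.  The deviation report lists, per band,
``delta = scale * theoretical - experimental`` and summarises the mean
absolute deviation over the bands that have an experimental value; bands
without one are listed but excluded from the summary.  No frequency scaling
is applied by default (``scale=1.0``): the comparison is against raw harmonic
values, as in the bundled reference table.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .shift_data import FormatError, ValidationError, _read_frame

__all__ = ["IRBandPair", "read_ir_table", "load_builtin_ir_bands", "band_deviation_table"]


@dataclass(frozen=True)
class IRBandPair:
    """One vibrational band: mode attribution, experimental wavenumber (cm^-1,
    None if unresolved) and theoretical wavenumbers keyed by
    (candidate, method)."""

    mode_label: str
    experimental: float | None
    theoretical: Mapping[tuple[str, str], float]
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.experimental is not None and self.experimental <= 0:
            raise ValidationError(f"non-positive wavenumber for {self.mode_label!r}")
        for key, v in self.theoretical.items():
            if v <= 0:
                raise ValidationError(f"non-positive wavenumber {v} for {key}")


def _parse_wavenumber(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in ("", "-", "nan"):
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"non-numeric wavenumber {text!r}") from None


def read_ir_table(source) -> list[IRBandPair]:
    """Read a wide band table: columns ``mode_label``, ``experimental``, then
    one ``candidate@method`` column per theoretical set."""
    frame = _read_frame(source)
    cols = {c.strip().lower(): c for c in frame.columns}
    if "mode_label" not in cols:
        raise FormatError("missing required column 'mode_label'")
    if "experimental" not in cols:
        raise FormatError("missing required column 'experimental'")
    theory_cols = [c for c in frame.columns
                   if c not in (cols["mode_label"], cols["experimental"])]
    bands: list[IRBandPair] = []
    for _, row in frame.iterrows():
        theo: dict[tuple[str, str], float] = {}
        for col in theory_cols:
            if "@" not in col:
                raise FormatError(f"theoretical column {col!r} is not 'candidate@method'")
            cand, meth = col.split("@", 1)
            v = _parse_wavenumber(row[col])
            if v is not None:
                theo[(cand.strip(), meth.strip())] = v
        bands.append(IRBandPair(str(row[cols["mode_label"]]).strip(),
                                _parse_wavenumber(row[cols["experimental"]]), theo))
    return bands


def load_builtin_ir_bands() -> list[IRBandPair]:
    """Bundled band attributions for the O/S/N series at B3LYP/6-31G(d,p)
    and B3LYP/6-31+G(d,p)."""
    with resources.files("shiftdiscrim.data").joinpath("ir_bands.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        return read_ir_table(fh)


def band_deviation_table(
    pairs: Iterable[IRBandPair],
    candidate: str,
    method: str,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Per-band deviation report for one candidate and level of theory.

    Returns a frame with columns mode_label, experimental, theoretical,
    scaled, delta; the attribute ``frame.attrs["mean_abs_deviation"]`` holds
    the summary over bands with an experimental value (NaN when none has
    one).  Band order does not affect the summary.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    pairs = list(pairs)
    known = {key for p in pairs for key in p.theoretical}
    if not any((candidate, method) in p.theoretical for p in pairs):
        raise ValidationError(
            f"no theoretical values for ({candidate!r}, {method!r}); "
            f"available: {sorted(known)}"
        )
    rows = []
    for p in pairs:
        theo = p.theoretical.get((candidate, method))
        if theo is None:
            continue
        scaled = scale * theo
        delta = scaled - p.experimental if p.experimental is not None else float("nan")
        rows.append({
            "mode_label": p.mode_label,
            "experimental": p.experimental if p.experimental is not None else float("nan"),
            "theoretical": theo,
            "scaled": scaled,
            "delta": delta,
        })
    frame = pd.DataFrame(rows,
                         columns=["mode_label", "experimental", "theoretical",
                                  "scaled", "delta"])
    with_exp = frame["delta"].dropna()
    frame.attrs["mean_abs_deviation"] = (
        float(with_exp.abs().mean()) if len(with_exp) else float("nan")
    )
    frame.attrs["n_compared"] = int(len(with_exp))
    return frame
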