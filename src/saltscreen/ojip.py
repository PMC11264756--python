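"""Fast chlorophyll-a fluorescence (OJIP) transients and the JIP test.

A dark-adapted leaf exposed to saturating light shows a polyphasic
fluorescence rise from the origin level F0 through the J (~2 ms) and
I (~30 ms) steps to the peak P (= FM).  The JIP test reduces a transient
to a handful of biophysical parameters:

* ``FvFm`` — maximum potential quantum efficiency of PSII, (FM−F0)/FM;
* ``VJ``   — relative variable fluorescence at the J step,
  (FJ−F0)/(FM−F0);
* ``M0``   — approximated initial slope of the relative variable
  fluorescence curve, 4·(F300µs−F0)/(FM−F0), per ms;
* ``PIabs`` — performance index on absorption basis, a product of terms
  expressing reaction-centre density, trapping probability and
  electron-transport probability.

Two PIabs variants are supported.  The ``standard`` variant uses the
canonical middle term (FM−F0)/F0::

    PIabs = [1 − F0/FM] / (M0/VJ) · (FM−F0)/F0 · (1−VJ)/VJ

The ``as_printed`` variant replaces the middle term with (FM/F0)/F0, a
dimensionally anomalous form that occurs in some published renderings of
the index; it is provided so that either convention can be reproduced.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTransient",
    "JipMarks",
    "JipParameters",
    "MarkConfig",
    "PiAbsVariant",
    "read_transients",
    "extract_marks",
    "fv_fm",
    "m0_vj",
    "pi_abs",
    "compute_parameters",
    "analyze_transients",
]


class OjipFormatError(ValueError):
    """Raised when a transient table is structurally unreadable."""


class OjipDataError(ValueError):
    """Raised when transient data violate a precondition."""


class PiAbsVariant(str, enum.Enum):
    """Which middle term enters the performance index."""

    standard = "standard"
    as_printed = "as_printed"


@dataclass(frozen=True)
class FluorescenceTransient:
    """A single time-resolved fluorescence induction curve.

    Parameters
    ----------
    sample_id : str
        Label of the measured sample (variety/replicate).
    times : ndarray
        Acquisition times in seconds, strictly increasing.
    values : ndarray
        Fluorescence intensities (arbitrary units), same length.
    """

    sample_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise OjipDataError("times and values must be 1-D and equal length")
        if len(t) < 2:
            raise OjipDataError(f"transient {self.sample_id!r}: need >= 2 points, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise OjipDataError(f"transient {self.sample_id!r}: times not strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise OjipDataError(f"transient {self.sample_id!r}: values must be finite and non-negative")


@dataclass(frozen=True)
class JipMarks:
    """Fluorescence read at the JIP-test mark times (arbitrary units)."""

    F0: float
    F300: float
    FJ: float
    FM: float

    def __post_init__(self) -> None:
        for name in ("F0", "F300", "FJ", "FM"):
            if getattr(self, name) <= 0:
                raise OjipDataError(f"{name} must be > 0")
        if self.FM < max(self.F0, self.F300, self.FJ):
            raise OjipDataError("FM must be the largest mark")


@dataclass(frozen=True)
class MarkConfig:
    """Mark times in seconds.  Defaults: F0 at 50 µs, F300 at 300 µs, FJ at 2 ms."""

    t_f0: float = 50e-6
    t_f300: float = 300e-6
    t_fj: float = 2e-3
    median_filter: bool = False  # optional 3-point median pre-filter


@dataclass(frozen=True)
class JipParameters:
    sample_id: str
    marks: JipMarks
    M0: float
    VJ: float
    FvFm: float
    PIabs: float
    variant: PiAbsVariant = PiAbsVariant.standard


# ---------------------------------------------------------------------------
# I/O

REQUIRED_COLUMNS = ("sample_id", "time_s", "fluorescence")


def read_transients(source: Union[str, TextIO]) -> list[FluorescenceTransient]:
    """Read a long-format transient table (CSV/TSV) into transients.

    Expects columns ``sample_id``, ``time_s``, ``fluorescence``.  Rows are
    grouped by sample, sorted by time; duplicate times within a sample are
    averaged.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise OjipFormatError(f"missing required column {col!r}")
    try:
        df["time_s"] = pd.to_numeric(df["time_s"])
        df["fluorescence"] = pd.to_numeric(df["fluorescence"])
    except (ValueError, TypeError) as exc:
        raise OjipFormatError(f"non-numeric data: {exc}") from exc
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        agg = grp.groupby("time_s", sort=True)["fluorescence"].mean()
        out.append(
            FluorescenceTransient(
                sample_id=str(sid),
                times=agg.index.to_numpy(dtype=float),
                values=agg.to_numpy(dtype=float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# mark extraction

def _interp_log_time(t: FluorescenceTransient, when: float, values: np.ndarray) -> float:
    # OJIP acquisition is log-spaced; interpolate linearly in log10(time)
    if when < t.times[0] or when > t.times[-1]:
        raise OjipDataError(
            f"mark time {when:g} s outside acquisition range "
            f"[{t.times[0]:g}, {t.times[-1]:g}] s for {t.sample_id!r}"
        )
    return float(np.interp(np.log10(when), np.log10(t.times), values))


def extract_marks(t: FluorescenceTransient, config: MarkConfig | None = None) -> JipMarks:
    """Read F0, F300 and FJ at the configured times; FM is the global maximum.

    Interpolation between samples is linear in log10(time).  Raises
    :class:`OjipDataError` for a degenerate (flat) transient or a mark time
    outside the acquisition window.
    """
    config = config or MarkConfig()
    vals = t.values
    if config.median_filter and len(vals) >= 3:
        padded = np.pad(vals, 1, mode="edge")
        vals = np.median(np.lib.stride_tricks.sliding_window_view(padded, 3), axis=1)
    f0 = _interp_log_time(t, config.t_f0, vals)
    f300 = _interp_log_time(t, config.t_f300, vals)
    fj = _interp_log_time(t, config.t_fj, vals)
    fm = float(vals.max())
    if fm <= f0:
        raise OjipDataError(f"degenerate transient {t.sample_id!r}: FM <= F0 (no variable fluorescence)")
    return JipMarks(F0=f0, F300=f300, FJ=fj, FM=fm)


# ---------------------------------------------------------------------------
# JIP parameters

def fv_fm(m: JipMarks) -> float:
    """Maximum potential quantum efficiency of PSII, (FM − F0)/FM."""
    if m.FM <= m.F0:
        raise OjipDataError("FvFm undefined: FM <= F0")
    return (m.FM - m.F0) / m.FM


def m0_vj(m: JipMarks) -> tuple[float, float]:
    """Initial slope M0 = 4(F300−F0)/(FM−F0) and J-step V_J = (FJ−F0)/(FM−F0)."""
    fv = m.FM - m.F0
    if fv <= 0:
        raise OjipDataError("M0/VJ undefined: FM <= F0")
    return 4.0 * (m.F300 - m.F0) / fv, (m.FJ - m.F0) / fv


def pi_abs(m: JipMarks, variant: PiAbsVariant | str = PiAbsVariant.standard) -> float:
    """Performance index on absorption basis.

    ``standard``:   [1 − F0/FM] / (M0/VJ) · (FM−F0)/F0 · (1−VJ)/VJ
    ``as_printed``: same with middle term (FM/F0)/F0.
    """
    variant = PiAbsVariant(variant)
    m0, vj = m0_vj(m)
    if not 0.0 < vj < 1.0:
        raise OjipDataError(f"PIabs undefined for VJ = {vj:g} (need 0 < VJ < 1)")
    if m0 <= 0:
        raise OjipDataError(f"PIabs undefined for M0 = {m0:g} (need M0 > 0)")
    first = (1.0 - m.F0 / m.FM) / (m0 / vj)
    last = (1.0 - vj) / vj
    if variant is PiAbsVariant.standard:
        middle = (m.FM - m.F0) / m.F0
    else:
        middle = (m.FM / m.F0) / m.F0
    return first * middle * last


def compute_parameters(
    t: FluorescenceTransient,
    config: MarkConfig | None = None,
    variant: PiAbsVariant | str = PiAbsVariant.standard,
) -> JipParameters:
    """Extract marks and compute the full JIP parameter set for one transient."""
    marks = extract_marks(t, config)
    m0, vj = m0_vj(marks)
    return JipParameters(
        sample_id=t.sample_id,
        marks=marks,
        M0=m0,
        VJ=vj,
        FvFm=fv_fm(marks),
        PIabs=pi_abs(marks, variant),
        variant=PiAbsVariant(variant),
    )


def analyze_transients(
    transients: Iterable[FluorescenceTransient],
    config: MarkConfig | None = None,
    variant: PiAbsVariant | str = PiAbsVariant.standard,
) -> pd.DataFrame:
    """Per-sample JIP marks and parameters as a tidy DataFrame."""
    rows = []
    for t in transients:
        p = compute_parameters(t, config, variant)
        rows.append(
            {
                "sample_id": p.sample_id,
                "F0": p.marks.F0,
                "F300": p.marks.F300,
                "FJ": p.marks.FJ,
                "FM": p.marks.FM,
                "M0": p.M0,
                "VJ": p.VJ,
                "FvFm": p.FvFm,
                "PIabs": p.PIabs,
                "variant": p.variant.value,
            }
        )
    return pd.DataFrame(rows)
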