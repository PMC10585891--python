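"""Stratified Lexis-diagram rate tables.

A Lexis diagram is a rectangular grid of event rates indexed by age group
(rows) and calendar period (columns); diagonals index birth cohorts
(cohort = period - age). This module holds the data model for G strata of
(event count, person-years) matrices sharing one grid, long-format CSV
serialization, and the observed cross-hazard rate-ratio (CH-RR)
diagnostics used to screen for proportionality patterns before modelling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LexisValidationError

# flag codes for RateRatioGrid cells
RR_OK = 0
RR_ZERO_NUM = 1  # 0/positive: ratio is 0, log-ratio undefined
RR_UNDEFINED = 2  # positive/0 or 0/0


@dataclass(frozen=True)
class LexisGrid:
    """Equal-interval age x period grid.

    Parameters
    ----------
    A, P : int
        Number of age groups and calendar periods (each at least 2).
    age_start, period_start : float
        Left edge (in years) of the first age group / calendar period.
    width : float
        Interval width in years, shared by the age and period axes. The
        cohort-diagonal algebra (cohort = period - age) requires equal
        widths; unequal-width tables are rejected upstream.
    """

    A: int
    P: int
    age_start: float = 0.0
    period_start: float = 0.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.A < 2 or self.P < 2:
            raise LexisValidationError(
                f"grid needs A >= 2 and P >= 2, got A={self.A}, P={self.P}"
            )
        if not self.width > 0:
            raise LexisValidationError(f"interval width must be > 0, got {self.width}")

    @property
    def C(self) -> int:
        """Number of birth-cohort diagonals, A + P - 1."""
        return self.A + self.P - 1

    @property
    def age_mids(self) -> np.ndarray:
        return self.age_start + self.width * (np.arange(self.A) + 0.5)

    @property
    def period_mids(self) -> np.ndarray:
        return self.period_start + self.width * (np.arange(self.P) + 0.5)

    @property
    def cohort_mids(self) -> np.ndarray:
        """Cohort midpoint years: period_mid - age_mid, oldest cohort first."""
        return (
            self.period_start
            - self.age_start
            + self.width * (np.arange(self.C) - (self.A - 1))
        )

    def cohort_index(self, a: np.ndarray | int, p: np.ndarray | int) -> np.ndarray | int:
        """1-based diagonal index k = (p - a) + A for 1-based a, p."""
        return (np.asarray(p) - np.asarray(a)) + self.A

    def cell_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-based (age, period, cohort) index for each cell, age-major order."""
        a = np.repeat(np.arange(1, self.A + 1), self.P)
        p = np.tile(np.arange(1, self.P + 1), self.A)
        return a, p, (p - a) + self.A


@dataclass(frozen=True)
class StratumData:
    """Event counts and person-years for one stratum on a grid.

    Counts are accepted as non-negative reals (not just integers) so that
    noiseless expected-count tables can be analyzed exactly.
    """

    label: str
    counts: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        offset = np.asarray(self.offset, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "offset", offset)
        if counts.ndim != 2 or counts.shape != offset.shape:
            raise LexisValidationError(
                f"stratum {self.label!r}: counts {counts.shape} and "
                f"person-years {offset.shape} must be matching 2-D arrays"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            a, p = np.argwhere((counts < 0) | ~np.isfinite(counts))[0] + 1
            raise LexisValidationError(
                f"stratum {self.label!r}: negative or non-finite count at "
                f"(age {a}, period {p})"
            )
        if np.any(offset <= 0) or not np.all(np.isfinite(offset)):
            a, p = np.argwhere((offset <= 0) | ~np.isfinite(offset))[0] + 1
            raise LexisValidationError(
                f"stratum {self.label!r}: person-years must be positive and "
                f"finite, offending cell (age {a}, period {p})"
            )

    @property
    def rates(self) -> np.ndarray:
        return self.counts / self.offset


@dataclass(frozen=True)
class StratifiedLexis:
    """G strata of aligned (counts, person-years) matrices on one grid."""

    grid: LexisGrid
    strata: tuple[StratumData, ...]

    def __post_init__(self) -> None:
        strata = tuple(self.strata)
        object.__setattr__(self, "strata", strata)
        if len(strata) < 1:
            raise LexisValidationError("need at least one stratum")
        labels = [s.label for s in strata]
        if len(set(labels)) != len(labels):
            raise LexisValidationError(f"duplicate stratum labels: {labels}")
        shape = (self.grid.A, self.grid.P)
        for s in strata:
            if s.counts.shape != shape:
                raise LexisValidationError(
                    f"stratum {s.label!r} has shape {s.counts.shape}, "
                    f"grid expects {shape}"
                )

    @property
    def G(self) -> int:
        return len(self.strata)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strata]

    def stratum(self, label: str) -> StratumData:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(f"unknown stratum label {label!r}; have {self.labels}")

    def subset(self, labels: Sequence[str]) -> "StratifiedLexis":
        """Restriction to the given strata, preserving the given order."""
        return StratifiedLexis(self.grid, tuple(self.stratum(l) for l in labels))


@dataclass(frozen=True)
class RateRatioGrid:
    """Observed cellwise cross-hazard rate ratios between two strata.

    ``flags`` marks cells where the ratio is zero (zero numerator) or
    undefined (zero denominator); such cells are carried, never dropped.
    """

    numerator_label: str
    denominator_label: str
    values: np.ndarray
    flags: np.ndarray
    grid: LexisGrid

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of cells with a finite positive ratio."""
        return self.flags == RR_OK

    def to_frame(self) -> pd.DataFrame:
        """Tidy table ``age_index, period_index, rr, flag`` (1-based indices)."""
        a, p, _ = self.grid.cell_indices()
        return pd.DataFrame(
            {
                "age_index": a,
                "period_index": p,
                "rr": self.values.ravel(),
                "flag": self.flags.ravel(),
            }
        )


@dataclass(frozen=True)
class RRDirectionSummary:
    """Mean within-row/column/diagonal variance of the log CH-RR.

    Zero dispersion along a direction is the observed-data signature of a
    proportionality regime: along diagonals for PH-L, along rows (periods
    within an age group) for PH-T, along columns (ages within a period)
    for PH-X, and along all three for PH-A.
    """

    row: float
    column: float
    diagonal: float

    def as_dict(self) -> dict[str, float]:
        return {"row": self.row, "column": self.column, "diagonal": self.diagonal}


_META_KEYS = ("width", "age_start", "period_start")
_COLUMNS = ["stratum", "age_index", "period_index", "count", "person_years"]


def write_rate_table(data: StratifiedLexis, path: str | Path) -> None:
    """Serialize to long-format CSV with a ``# key: value`` metadata header.

    One row per stratum x age x period cell; 1-based indices; the
    round-trip through :func:`read_rate_table` is exact.
    """
    g = data.grid
    buf = io.StringIO()
    for key in _META_KEYS:
        buf.write(f"# {key}: {getattr(g, key)!r}\n")
    rows = []
    a_idx, p_idx, _ = g.cell_indices()
    for s in data.strata:
        rows.append(
            pd.DataFrame(
                {
                    "stratum": s.label,
                    "age_index": a_idx,
                    "period_index": p_idx,
                    "count": s.counts.ravel(),
                    "person_years": s.offset.ravel(),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_rate_table(path: str | Path) -> StratifiedLexis:
    """Parse a long-format rate-table CSV into a validated StratifiedLexis.

    Grid metadata comes from the leading ``# key: value`` comment block;
    A and P are inferred from the distinct 1-based indices present. Every
    stratum must cover the complete A x P grid exactly once.
    """
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, float] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                meta[key.strip()] = float(val.strip().strip("'\""))
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    missing_cols = set(_COLUMNS) - set(df.columns)
    if missing_cols:
        raise LexisValidationError(f"missing columns: {sorted(missing_cols)}")
    if df.empty:
        raise LexisValidationError("rate table contains no data rows")

    A = int(df["age_index"].max())
    P = int(df["period_index"].max())
    grid = LexisGrid(
        A=A,
        P=P,
        age_start=float(meta.get("age_start", 0.0)),
        period_start=float(meta.get("period_start", 0.0)),
        width=float(meta.get("width", 1.0)),
    )

    strata = []
    for label, sub in df.groupby("stratum", sort=False):
        dup = sub.duplicated(subset=["age_index", "period_index"])
        if dup.any():
            r = sub[dup].iloc[0]
            raise LexisValidationError(
                f"stratum {label!r}: duplicate cell "
                f"(age {int(r.age_index)}, period {int(r.period_index)})"
            )
        if len(sub) != A * P:
            have = set(zip(sub["age_index"], sub["period_index"]))
            want = {(a, p) for a in range(1, A + 1) for p in range(1, P + 1)}
            missing = sorted(want - have)
            raise LexisValidationError(
                f"stratum {label!r}: missing cell(s) (age, period) = {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        counts = np.zeros((A, P))
        offset = np.zeros((A, P))
        ai = sub["age_index"].to_numpy(int) - 1
        pi = sub["period_index"].to_numpy(int) - 1
        counts[ai, pi] = sub["count"].to_numpy(float)
        offset[ai, pi] = sub["person_years"].to_numpy(float)
        strata.append(StratumData(str(label), counts, offset))
    return StratifiedLexis(grid, tuple(strata))


def cross_hazard_rr(data: StratifiedLexis, j: str, k: str) -> RateRatioGrid:
    """Observed cellwise CH-RR of stratum ``j`` over stratum ``k``.

    CH-RRs are *floating* rate ratios (no referent category): each cell is
    the empirical rate of j divided by the empirical rate of k.
    """
    if j == k:
        raise LexisValidationError("numerator and denominator strata must differ")
    num = data.stratum(j).rates
    den = data.stratum(k).rates
    flags = np.full(num.shape, RR_OK, dtype=int)
    flags[(num == 0) & (den > 0)] = RR_ZERO_NUM
    flags[den == 0] = RR_UNDEFINED
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(flags == RR_UNDEFINED, np.nan, num / np.where(den == 0, np.nan, den))
    return RateRatioGrid(j, k, values, flags, data.grid)


def summarize_rr_directions(rr: RateRatioGrid) -> RRDirectionSummary:
    """Dispersion of the log CH-RR along rows, columns, and diagonals.

    Returns the mean within-group variance of log CH-RR over defined cells,
    grouping by age row, period column, and cohort diagonal in turn. A
    descriptive screen: the direction(s) with (near-)zero dispersion point
    at the candidate proportionality regime.
    """
    mask = rr.defined & (rr.values > 0)
    if not mask.any():
        raise LexisValidationError("all CH-RR cells are undefined or zero")
    logv = np.where(mask, np.log(np.where(mask, rr.values, 1.0)), np.nan)
    a, p, c = rr.grid.cell_indices()
    flat = logv.ravel()

    def mean_within(groups: np.ndarray) -> float:
        out = []
        for gval in np.unique(groups):
            vals = flat[(groups == gval) & np.isfinite(flat)]
            if vals.size >= 1:
                out.append(float(np.var(vals)))
        return float(np.mean(out))

    return RRDirectionSummary(
        row=mean_within(a), column=mean_within(p), diagonal=mean_within(c)
    )
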