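"""Box-Cox-Cole-Green (BCCG) distribution and LMS centile arithmetic.

The LMS method summarises how a positive measurement (here birth weight in
grams) varies with age (here gestational age in completed weeks) through
three quantities: a Box-Cox power ``L`` that removes skewness, the median
``M``, and the coefficient of variation ``S``.  Given a triple ``(L, M, S)``
the measurement ``x`` maps to a standard-normal z-score

    z = ((x / M)**L - 1) / (L * S)            (L != 0)
    z = log(x / M) / S                        (L == 0)

and conversely the centile at z is ``M * (1 + L*S*z)**(1/L)`` (or
``M * exp(S*z)`` in the L -> 0 limit).  The BCCG distribution is the law of
``x`` under which this z is standard normal.

The small truncation correction that would renormalise the density to the
positive half-line (a factor ``Phi(1/(L*S))``) is deliberately omitted: for
the coefficients of variation seen in anthropometry (S below ~0.3) it is
smaller than 1e-8 and the classical LMS formulation ignores it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LMSTriple",
    "CentileSpec",
    "DEFAULT_CENTILES",
    "LMSTable",
    "CentileTable",
    "DomainError",
    "InvalidParameterError",
    "centile_value",
    "zscore_value",
    "bccg_logdensity",
    "bccg_cdf",
    "bccg_quantile",
    "make_centile_table",
    "interpolate_lms",
    "round_half_away",
]

# Below this magnitude of L the log-limit branch is used: Table-style charts
# carry L rounded to two decimals and values of order 1e-2 must still go
# through the power branch, while exactly-zero L must not divide by zero.
_L_EPS = 1e-8

SEXES = ("M", "F")


class DomainError(ValueError):
    """The requested evaluation lies outside the BCCG support, i.e. 1 + L*S*z <= 0."""


class InvalidParameterError(ValueError):
    """An LMS parameter violates M > 0, S > 0 (or a weight x <= 0 was supplied)."""


@dataclass(frozen=True)
class LMSTriple:
    """One (L, M, S) parameter triple.

    Parameters
    ----------
    L : float
        Box-Cox power (dimensionless; may be negative or zero).
    M : float
        Median, in measurement units (grams here); must be positive.
    S : float
        Coefficient of variation (dimensionless); must be positive.
    """

    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not (self.M > 0):
            raise InvalidParameterError(f"median M must be positive, got {self.M}")
        if not (self.S > 0):
            raise InvalidParameterError(
                f"coefficient of variation S must be positive, got {self.S}"
            )


@dataclass(frozen=True)
class CentileSpec:
    """An ordered set of labelled centile lines, defined by their z values.

    Labels are display names ("2nd", "50th", ...); the z values, not the
    labels, define the lines.  The default seven-line spec uses the
    two-thirds-of-an-SD spacing z = 0, +/-2/3, +/-4/3, +/-2, labelled with
    the approximate centiles they correspond to.
    """

    labels: tuple[str, ...]
    z: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.z) or not self.labels:
            raise ValueError("labels and z must be non-empty and equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("centile labels must be unique")
        if not all(a < b for a, b in zip(self.z, self.z[1:])):
            raise ValueError("z values must be strictly increasing")

    def __iter__(self):
        return iter(zip(self.labels, self.z))

    def __len__(self) -> int:
        return len(self.labels)


DEFAULT_CENTILES = CentileSpec(
    labels=("2nd", "9th", "25th", "50th", "75th", "91st", "98th"),
    z=(-2.0, -4.0 / 3.0, -2.0 / 3.0, 0.0, 2.0 / 3.0, 4.0 / 3.0, 2.0),
)


def centile_value(lms: LMSTriple, z: float) -> float:
    """Measurement value at standard-normal position ``z``.

    Evaluates ``M * (1 + L*S*z)**(1/L)``, or the analytic limit
    ``M * exp(S*z)`` when ``|L| < 1e-8``.  Raises :class:`DomainError` when
    ``1 + L*S*z <= 0`` (the centile is undefined for that triple/z).
    """
    L, M, S = lms.L, lms.M, lms.S
    if abs(L) < _L_EPS:
        return M * float(np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0.0:
        raise DomainError(
            f"centile undefined: 1 + L*S*z = {base:.6g} <= 0 for L={L}, S={S}, z={z}"
        )
    # log1p form keeps full precision for small L (equivalent to base**(1/L))
    return M * float(np.exp(np.log1p(L * S * z) / L))


def zscore_value(x: float, lms: LMSTriple) -> float:
    """z-score (SD score) of measurement ``x`` under the triple.

    Exact inverse of :func:`centile_value` on its domain:
    ``((x/M)**L - 1) / (L*S)``, with the log-limit ``log(x/M)/S`` at L ~ 0.
    """
    if not (x > 0):
        raise InvalidParameterError(f"measurement must be positive, got {x}")
    L, M, S = lms.L, lms.M, lms.S
    if abs(L) < _L_EPS:
        return float(np.log(x / M) / S)
    # expm1 form of ((x/M)**L - 1)/(L*S), exact inverse of centile_value
    return float(np.expm1(L * np.log(x / M)) / (L * S))


def bccg_logdensity(x: float, lms: LMSTriple) -> float:
    """Log density of the BCCG distribution at ``x`` (truncation omitted).

    Change-of-variables density of the Box-Cox transform:
    ``log f(x) = -z^2/2 - log(2*pi)/2 + (L-1)*log(x/M) - log(S) - log(M)``.
    """
    if not (x > 0):
        raise InvalidParameterError(f"measurement must be positive, got {x}")
    z = zscore_value(x, lms)
    L, M, S = lms.L, lms.M, lms.S
    return float(
        -0.5 * z * z
        - 0.5 * np.log(2.0 * np.pi)
        + (L - 1.0) * np.log(x / M)
        - np.log(S)
        - np.log(M)
    )


def bccg_cdf(x: float, lms: LMSTriple) -> float:
    """P(X <= x) = Phi(z(x))."""
    return float(norm.cdf(zscore_value(x, lms)))


def bccg_quantile(p: float, lms: LMSTriple) -> float:
    """Inverse CDF: the measurement below which a fraction ``p`` falls."""
    if not (0.0 < p < 1.0):
        raise InvalidParameterError(f"probability must lie in (0, 1), got {p}")
    return centile_value(lms, float(norm.ppf(p)))


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (2302.5 -> 2303), elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out if out.ndim else float(out)


class LMSTable:
    """(L, M, S) triples on a gap-free grid of integer gestational weeks.

    Holds one triple per (sex, completed week); every sex present must cover
    the identical contiguous week range.  Sexes are coded ``"M"``/``"F"``.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "week", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        frame = frame.loc[:, ["sex", "week", "L", "M", "S"]].copy()
        frame["week"] = frame["week"].astype(int)
        for sex in frame["sex"].unique():
            if sex not in SEXES:
                raise ValueError(f"unknown sex code {sex!r}; expected one of {SEXES}")
        if frame.duplicated(["sex", "week"]).any():
            raise ValueError("duplicate (sex, week) rows in LMS table")
        sexes = tuple(s for s in SEXES if s in set(frame["sex"]))
        if not sexes:
            raise ValueError("LMS table holds no rows")
        lo, hi = int(frame["week"].min()), int(frame["week"].max())
        gaps = []
        for sex in sexes:
            have = set(frame.loc[frame["sex"] == sex, "week"])
            gaps.extend((sex, w) for w in range(lo, hi + 1) if w not in have)
        if gaps:
            raise ValueError(f"LMS table has gaps at (sex, week): {gaps}")
        for _, row in frame.iterrows():
            LMSTriple(row["L"], row["M"], row["S"])  # validates M > 0, S > 0
        frame = frame.sort_values(["week", "sex"], key=_sex_sort_key).reset_index(
            drop=True
        )
        self._frame = frame
        self.sexes = sexes
        self.week_range = (lo, hi)
        self._lookup = {
            (r.sex, int(r.week)): LMSTriple(r.L, r.M, r.S)
            for r in frame.itertuples()
        }

    @classmethod
    def from_dict(
        cls, triples: Mapping[tuple[str, int], LMSTriple | tuple[float, float, float]]
    ) -> "LMSTable":
        rows = []
        for (sex, week), t in triples.items():
            L, M, S = (t.L, t.M, t.S) if isinstance(t, LMSTriple) else t
            rows.append({"sex": sex, "week": int(week), "L": L, "M": M, "S": S})
        return cls(pd.DataFrame(rows))

    @property
    def weeks(self) -> range:
        return range(self.week_range[0], self.week_range[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def triple(self, sex: str, week: int) -> LMSTriple:
        try:
            return self._lookup[(sex, int(week))]
        except KeyError:
            raise KeyError(f"no LMS triple for sex={sex!r}, week={week}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, LMSTable):
            return NotImplemented
        return self._lookup == other._lookup

    def __repr__(self) -> str:
        lo, hi = self.week_range
        return f"LMSTable(sexes={self.sexes}, weeks={lo}..{hi})"


def _sex_sort_key(col):
    if col.name == "sex":
        return col.map({"M": 0, "F": 1})
    return col


def interpolate_lms(table: LMSTable, sex: str, t: float) -> LMSTriple:
    """Triple at a non-integer gestation ``t`` (exact weeks).

    Linear interpolation in t of L, of log M, and of log S between adjacent
    integer weeks; exact at the knots.  The log scale preserves positivity
    and matches the log link used for the median when fitting.
    """
    lo, hi = table.week_range
    if not (lo <= t <= hi):
        raise ValueError(f"gestation {t} outside table range {lo}..{hi}")
    w0 = int(np.floor(t))
    if t == w0:
        return table.triple(sex, w0)
    a = table.triple(sex, w0)
    b = table.triple(sex, w0 + 1)
    f = t - w0
    return LMSTriple(
        L=(1 - f) * a.L + f * b.L,
        M=float(np.exp((1 - f) * np.log(a.M) + f * np.log(b.M))),
        S=float(np.exp((1 - f) * np.log(a.S) + f * np.log(b.S))),
    )


class CentileTable:
    """Centile chart: per sex, a weeks x centile-labels matrix of integer grams."""

    def __init__(self, frames: Mapping[str, pd.DataFrame], labels: Sequence[str]):
        self.labels = tuple(labels)
        self.frames = {}
        for sex, df in frames.items():
            if list(df.columns) != list(self.labels):
                raise ValueError(f"centile columns for sex {sex} do not match labels")
            self.frames[sex] = df.copy()
        self.sexes = tuple(s for s in SEXES if s in self.frames)

    def frame(self, sex: str) -> pd.DataFrame:
        return self.frames[sex]

    def __repr__(self) -> str:
        weeks = {s: (int(df.index.min()), int(df.index.max())) for s, df in self.frames.items()}
        return f"CentileTable(sexes={self.sexes}, weeks={weeks}, labels={self.labels})"


def make_centile_table(
    table: LMSTable, spec: CentileSpec = DEFAULT_CENTILES
) -> CentileTable:
    """Tabulate centiles for every (sex, week) in ``table``.

    Applies :func:`centile_value` cell-wise and rounds half-away-from-zero to
    integer grams.  A domain error in any cell is re-raised naming the
    offending (sex, week, label).
    """
    frames = {}
    for sex in table.sexes:
        rows = {}
        for week in table.weeks:
            lms = table.triple(sex, week)
            vals = []
            for label, z in spec:
                try:
                    vals.append(round_half_away(centile_value(lms, z)))
                except DomainError as err:
                    raise DomainError(
                        f"centile undefined at sex={sex}, week={week}, "
                        f"label={label!r}: {err}"
                    ) from err
            rows[week] = vals
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(spec.labels))
        df.index.name = "week"
        frames[sex] = df.astype(int)
    return CentileTable(frames, spec.labels)
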