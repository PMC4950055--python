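"""Seeded synthetic birth registers with the structure the analysis assumes.

The generator emulates a national cytogenetic register of Down syndrome
births: for each (sex, completed week) cell it emits an exact configured
number of clean live-birth free-trisomy-21 records whose weights are drawn
from the generating LMS chart (a standard-normal z pushed through the
centile transform, redrawn in the negligible event that 1 + L*S*z <= 0, so
the BCCG shape is preserved).  Optional knobs add a linear secular trend in
grams per year, missingness in weight and/or gestation (MCAR or with a
log-odds-per-week gradient), and contaminating records (non-live outcomes,
non-free-trisomy karyotypes) that the selection stage must remove.

Counts are deterministic per cell rather than multinomial, so register
totals and selection flows are exactly assertable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bccg import LMSTable
from .reference import reference_counts, reference_lms_table

__all__ = ["SimulationConfig", "simulate_register", "RECORD_COLUMNS"]

RECORD_COLUMNS = ["sex", "gest_weeks", "weight_g", "year", "outcome", "karyotype"]

OUTCOMES = ("live_birth", "stillbirth", "termination")
KARYOTYPES = ("free_trisomy_21", "translocation", "mosaic", "other")

# Week anchoring the missingness log-odds gradient (the modal gestation).
_MISSING_REF_WEEK = 38


@dataclass
class SimulationConfig:
    """Generative specification of a synthetic register.

    Defaults reproduce the reference register: the published per-(sex, week)
    counts (n = 8,825) and LMS parameters for weeks 28-43, birth years
    uniform over 1989-2011, no secular trend, no missingness, no
    contamination.

    Attributes
    ----------
    count_table : DataFrame with columns sex, week, n
        Exact number of clean records per cell.
    lms_table : LMSTable
        Generating truth for the weight distributions.
    year_range : (int, int)
        Birth years, drawn uniformly (inclusive).
    trend_g_per_year : float
        Added to each weight as ``trend * (year - midpoint(year_range))``.
    missing_weight_rate, missing_gestation_rate : float
        Marginal missingness probabilities (at the reference week 38 for
        weight when a gradient is set).
    missingness_gestation_slope : float
        Log-odds change in weight-missingness per week of gestation
        (requires missing_weight_rate > 0 to have any effect).
    non_live_fraction : float
        Extra stillbirth/termination records appended, as a fraction of the
        clean total.
    non_free_trisomy_fraction : float
        Extra live births with translocation/mosaic/other karyotypes.
    stillbirth_weight_offset_g : float
        Added to stillbirth weights (the deficit of stillborn babies is
        unpublished; this knob is an arbitrary default, not a claim).
    seed : int
    """

    count_table: pd.DataFrame = field(default_factory=reference_counts)
    lms_table: LMSTable = field(default_factory=reference_lms_table)
    year_range: tuple[int, int] = (1989, 2011)
    trend_g_per_year: float = 0.0
    missing_weight_rate: float = 0.0
    missing_gestation_rate: float = 0.0
    missingness_gestation_slope: float = 0.0
    non_live_fraction: float = 0.0
    non_free_trisomy_fraction: float = 0.0
    stillbirth_weight_offset_g: float = -150.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "missing_weight_rate",
            "missing_gestation_rate",
            "non_live_fraction",
            "non_free_trisomy_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        ct = self.count_table
        if not {"sex", "week", "n"} <= set(ct.columns):
            raise ValueError("count_table needs columns sex, week, n")
        if (ct["n"] < 0).any():
            raise ValueError("counts must be non-negative")
        lo, hi = self.lms_table.week_range
        weeks = ct["week"].astype(int)
        if (weeks < lo).any() or (weeks > hi).any():
            raise ValueError("count_table weeks outside the LMS table's range")
        for sex in ct["sex"].unique():
            if sex not in self.lms_table.sexes:
                raise ValueError(f"count_table sex {sex!r} absent from LMS table")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("invalid year_range")
        if self.missingness_gestation_slope != 0.0 and self.missing_weight_rate == 0.0:
            raise ValueError(
                "missingness_gestation_slope needs missing_weight_rate > 0"
            )


def _draw_weights(rng: np.random.Generator, n: int, L: float, M: float, S: float) -> np.ndarray:
    """n BCCG draws: z ~ N(0,1) through the centile transform, rejecting the
    (practically impossible at chart parameters) region 1 + L*S*z <= 0."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        z = rng.standard_normal(todo.size)
        if abs(L) < 1e-8:
            out[todo] = M * np.exp(S * z)
            break
        base = 1.0 + L * S * z
        good = base > 0
        out[todo[good]] = M * base[good] ** (1.0 / L)
        todo = todo[~good]
    return out


def simulate_register(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Generate a register as a DataFrame with :data:`RECORD_COLUMNS`.

    Byte-identical output for identical configs (cells are processed in
    sorted (week, sex M-before-F) order from a single seeded generator).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range
    mid = 0.5 * (y0 + y1)

    cells = config.count_table.copy()
    cells["_sex_order"] = cells["sex"].map({"M": 0, "F": 1})
    cells = cells.sort_values(["week", "_sex_order"])

    parts = []
    for row in cells.itertuples():
        n = int(row.n)
        if n == 0:
            continue
        trip = config.lms_table.triple(row.sex, int(row.week))
        w = _draw_weights(rng, n, trip.L, trip.M, trip.S)
        years = rng.integers(y0, y1 + 1, size=n)
        w = w + config.trend_g_per_year * (years - mid)
        parts.append(
            pd.DataFrame(
                {
                    "sex": row.sex,
                    "gest_weeks": int(row.week),
                    "weight_g": w,
                    "year": years,
                    "outcome": "live_birth",
                    "karyotype": "free_trisomy_21",
                }
            )
        )
    clean = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=RECORD_COLUMNS)
    n_clean = len(clean)

    # missingness on the clean records
    if config.missing_weight_rate > 0 and n_clean:
        p0 = config.missing_weight_rate
        logit = np.log(p0 / (1 - p0)) + config.missingness_gestation_slope * (
            clean["gest_weeks"].to_numpy(float) - _MISSING_REF_WEEK
        )
        p = 1.0 / (1.0 + np.exp(-logit))
        clean.loc[rng.random(n_clean) < p, "weight_g"] = np.nan
    if config.missing_gestation_rate > 0 and n_clean:
        hit = rng.random(n_clean) < config.missing_gestation_rate
        clean["gest_weeks"] = clean["gest_weeks"].astype("Int64")
        clean.loc[hit, "gest_weeks"] = pd.NA

    extras = []
    probs = cells["n"].to_numpy(float)
    if probs.sum() > 0:
        probs = probs / probs.sum()

        def _contaminants(n_extra: int, live: bool) -> pd.DataFrame:
            idx = rng.choice(len(cells), size=n_extra, p=probs)
            rows = []
            for i in idx:
                cell = cells.iloc[i]
                trip = config.lms_table.triple(cell["sex"], int(cell["week"]))
                w = float(_draw_weights(rng, 1, trip.L, trip.M, trip.S)[0])
                if live:
                    outcome = "live_birth"
                    karyo = KARYOTYPES[1 + rng.choice(3, p=[0.45, 0.45, 0.10])]
                else:
                    outcome = "stillbirth" if rng.random() < 0.5 else "termination"
                    karyo = "free_trisomy_21"
                    if outcome == "stillbirth":
                        w = max(w + config.stillbirth_weight_offset_g, 50.0)
                rows.append(
                    {
                        "sex": cell["sex"],
                        "gest_weeks": int(cell["week"]),
                        "weight_g": w,
                        "year": int(rng.integers(y0, y1 + 1)),
                        "outcome": outcome,
                        "karyotype": karyo,
                    }
                )
            return pd.DataFrame(rows)

        n_nonlive = int(round(config.non_live_fraction * n_clean))
        n_nonfree = int(round(config.non_free_trisomy_fraction * n_clean))
        if n_nonlive:
            extras.append(_contaminants(n_nonlive, live=False))
        if n_nonfree:
            extras.append(_contaminants(n_nonfree, live=True))

    out = pd.concat([clean, *extras], ignore_index=True)
    out = out.reindex(columns=RECORD_COLUMNS)
    out["gest_weeks"] = out["gest_weeks"].astype("Int64")
    out["year"] = out["year"].astype(int)
    return out
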