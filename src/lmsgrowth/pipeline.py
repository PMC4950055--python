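"""End-to-end chart construction: selection, fitting, tables, checks.

Mirrors the register analysis workflow: filter the raw register down to
live births with free trisomy 21 and complete data inside the fit window
(reporting a per-stage flow), fit the LMS curves, tabulate the chart,
summarise the sex difference and modal gestation, test for a secular trend
in SD scores and for an association between gestation and missing weight,
and optionally compare the fitted chart with an external reference chart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bccg import CentileSpec, CentileTable, DEFAULT_CENTILES, LMSTable, centile_value, make_centile_table
from .model import FitConfig, LMSModel, LMSResults, SexDifference
from .simulate import SimulationConfig, simulate_register

__all__ = [
    "SelectionReport",
    "TrendResult",
    "MissingnessResult",
    "ComparisonResult",
    "PipelineReport",
    "select_records",
    "modal_gestation",
    "secular_trend",
    "missingness_association",
    "compare_to_reference",
    "run_pipeline",
]

STAGES = ("live_birth", "free_trisomy_21", "complete_data", "within_window")


@dataclass(frozen=True)
class SelectionReport:
    """Per-stage record flow of the selection filter.

    ``total = retained + sum(excluded.values())`` always holds; stages are
    applied in the fixed order outcome -> karyotype -> completeness ->
    gestation window so each exclusion is charged to one stage.
    """

    total: int
    excluded: dict[str, int]
    retained: int

    def __post_init__(self) -> None:
        if self.total != self.retained + sum(self.excluded.values()):
            raise ValueError("selection counts do not conserve records")

    def to_dict(self) -> dict:
        return {"total": self.total, "excluded": dict(self.excluded), "retained": self.retained}


def select_records(
    records: pd.DataFrame, week_range: tuple[int, int] = (28, 43)
) -> tuple[pd.DataFrame, SelectionReport]:
    """Apply the inclusion filters in order and account for every record."""
    total = len(records)
    excluded: dict[str, int] = {}
    df = records
    keep = df["outcome"] == "live_birth"
    excluded["live_birth"] = int((~keep).sum())
    df = df[keep]
    keep = df["karyotype"] == "free_trisomy_21"
    excluded["free_trisomy_21"] = int((~keep).sum())
    df = df[keep]
    complete = df["weight_g"].notna() & df["gest_weeks"].notna()
    excluded["complete_data"] = int((~complete).sum())
    df = df[complete]
    weeks = df["gest_weeks"].astype(float)
    in_window = (weeks >= week_range[0]) & (weeks <= week_range[1])
    excluded["within_window"] = int((~in_window).sum())
    df = df[in_window]
    return df.reset_index(drop=True), SelectionReport(total, excluded, len(df))


@dataclass(frozen=True)
class ModalGestation:
    week: int
    histogram: pd.Series


def modal_gestation(records: pd.DataFrame) -> ModalGestation:
    """Completed week with the most births; ties break toward the lower week."""
    weeks = records["gest_weeks"].dropna().astype(int)
    if weeks.empty:
        raise ValueError("no gestational ages present")
    hist = weeks.value_counts().sort_index()
    return ModalGestation(week=int(hist.idxmax()), histogram=hist)


@dataclass(frozen=True)
class TrendResult:
    """Secular trend of birth weight across calendar years.

    The primary regression is of SD score on year; the grams-per-year
    conversion multiplies the SD-score slope by M*S at the modal week
    (an approximate SD in grams), averaged over the sexes present.
    """

    slope_sd_per_year: float
    ci_sd: tuple[float, float]
    slope_g_per_year: float
    ci_g: tuple[float, float]
    n: int
    scale: str = "zscore"


def secular_trend(
    records: pd.DataFrame, results: LMSResults, on: str = "zscore"
) -> TrendResult:
    """OLS regression of SD score (or raw grams, ``on="grams"``) on birth year."""
    df = records.dropna(subset=["weight_g", "gest_weeks"])
    years = df["year"].astype(float).to_numpy()
    if np.unique(years).size < 3:
        raise ValueError("need >= 3 distinct birth years for a trend regression")
    if on == "zscore":
        resp = results.zscore(
            df["weight_g"].to_numpy(float),
            df["gest_weeks"].astype(float).to_numpy(),
            df["sex"].to_numpy(object),
        )
    elif on == "grams":
        resp = df["weight_g"].to_numpy(float)
    else:
        raise ValueError("on must be 'zscore' or 'grams'")
    ols = sm.OLS(resp, sm.add_constant(years)).fit()
    slope, se = float(ols.params[1]), float(ols.bse[1])
    ci = (slope - 1.96 * se, slope + 1.96 * se)

    modal = modal_gestation(df).week
    factors = []
    for sex in ("M", "F"):
        if (df["sex"] == sex).any():
            trip = results.triple(sex, modal)
            factors.append(trip.M * trip.S)
    g_per_sd = float(np.mean(factors)) if on == "zscore" else 1.0
    return TrendResult(
        slope_sd_per_year=slope if on == "zscore" else slope / g_per_sd,
        ci_sd=ci if on == "zscore" else (ci[0] / g_per_sd, ci[1] / g_per_sd),
        slope_g_per_year=slope * g_per_sd if on == "zscore" else slope,
        ci_g=(ci[0] * g_per_sd, ci[1] * g_per_sd),
        n=len(df),
        scale=on,
    )


@dataclass(frozen=True)
class MissingnessResult:
    """Logistic regression of the missing-weight indicator on gestational week."""

    slope_per_week: float
    se: float
    p_value: float
    n: int


def missingness_association(records: pd.DataFrame) -> MissingnessResult:
    """Wald test for a gestation gradient in weight-missingness.

    Fits missing-weight ~ gestational week by Newton-Raphson (tolerance
    1e-10) among records with known gestation.
    """
    df = records.dropna(subset=["gest_weeks"])
    y = df["weight_g"].isna().to_numpy(float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError(
            "degenerate outcome: need both missing and observed weights"
        )
    X = sm.add_constant(df["gest_weeks"].astype(float).to_numpy())
    try:
        fit = sm.Logit(y, X).fit(method="newton", tol=1e-10, maxiter=100, disp=0)
    except Exception as err:  # perfect separation and kin
        raise ValueError(f"logistic regression failed: {err}") from err
    return MissingnessResult(
        slope_per_week=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(y.size),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Per-(sex, week) differences, reference minus study, over the overlap.

    ``table`` has columns sex, week, median_diff and one ``diff_<label>``
    column per centile line.  Swapping the two charts negates every value.
    """

    table: pd.DataFrame

    def median_difference(self, sex: str, week: int) -> float:
        t = self.table
        row = t[(t["sex"] == sex) & (t["week"] == week)]
        if row.empty:
            raise KeyError(f"no overlap at sex={sex}, week={week}")
        return float(row["median_diff"].iloc[0])


def compare_to_reference(
    study: LMSTable, reference: LMSTable, spec: CentileSpec = DEFAULT_CENTILES
) -> ComparisonResult:
    """Centile-by-centile difference between two LMS charts (reference - study)."""
    lo = max(study.week_range[0], reference.week_range[0])
    hi = min(study.week_range[1], reference.week_range[1])
    sexes = [s for s in study.sexes if s in reference.sexes]
    if lo > hi or not sexes:
        raise ValueError("charts have no overlapping (sex, week) domain")
    rows = []
    for sex in sexes:
        for week in range(lo, hi + 1):
            a = study.triple(sex, week)
            b = reference.triple(sex, week)
            row = {"sex": sex, "week": week, "median_diff": b.M - a.M}
            for label, z in spec:
                row[f"diff_{label}"] = centile_value(b, z) - centile_value(a, z)
            rows.append(row)
    return ComparisonResult(pd.DataFrame(rows))


@dataclass
class PipelineReport:
    """Everything the full analysis produces in one bundle."""

    selection: SelectionReport
    results: LMSResults
    lms_table: LMSTable
    centiles: CentileTable
    sex_difference: SexDifference | None
    modal: ModalGestation
    trend: TrendResult | None
    missingness: MissingnessResult | None
    comparison: ComparisonResult | None


def run_pipeline(
    records: pd.DataFrame | None = None,
    sim_config: SimulationConfig | None = None,
    fit_config: FitConfig | None = None,
    reference: LMSTable | None = None,
    spec: CentileSpec = DEFAULT_CENTILES,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Selection -> fit -> chart -> summaries -> optional reference comparison.

    Give either raw ``records`` or a :class:`SimulationConfig` to generate
    them.  With ``out_dir``, all tables and a JSON summary are written
    (deterministically: no timestamps, stable row order).
    """
    if records is None:
        if sim_config is None:
            sim_config = SimulationConfig()
        records = simulate_register(sim_config)
    fit_config = fit_config or FitConfig()

    stage = "selection"
    try:
        retained, selection = select_records(records, fit_config.week_range_fit)
        stage = "fit"
        model = LMSModel.from_dataframe(retained, fit_config)
        results = model.fit()
        stage = "evaluate"
        lms_table = results.lms_table()
        centiles = results.centile_table(spec)
        sexdiff = results.sex_difference_percent() if fit_config.sex_offset else None
        stage = "summaries"
        modal = modal_gestation(retained)
        complete_gest = records.dropna(subset=["gest_weeks"])
        trend = None
        if np.unique(retained["year"]).size >= 3:
            trend = secular_trend(retained, results)
        missing = None
        miss_ind = complete_gest["weight_g"].isna()
        if miss_ind.any() and not miss_ind.all():
            missing = missingness_association(records)
        stage = "comparison"
        comparison = compare_to_reference(lms_table, reference, spec) if reference is not None else None
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report = PipelineReport(
        selection=selection,
        results=results,
        lms_table=lms_table,
        centiles=centiles,
        sex_difference=sexdiff,
        modal=modal,
        trend=trend,
        missingness=missing,
        comparison=comparison,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    from . import io as lms_io

    out_dir.mkdir(parents=True, exist_ok=True)
    lms_io.write_lms_table(report.lms_table, out_dir / "lms_table.tsv")
    for sex in report.centiles.sexes:
        lms_io.write_centile_table(report.centiles, sex, out_dir / f"centiles_{sex}.tsv")
    summary = {
        "selection": report.selection.to_dict(),
        "fit": report.results.diagnostics(),
        "modal_gestation_weeks": report.modal.week,
    }
    if report.trend is not None:
        summary["secular_trend"] = {
            "slope_sd_per_year": report.trend.slope_sd_per_year,
            "ci_sd": list(report.trend.ci_sd),
            "slope_g_per_year": report.trend.slope_g_per_year,
            "ci_g": list(report.trend.ci_g),
            "n": report.trend.n,
        }
    if report.missingness is not None:
        summary["missingness"] = {
            "slope_per_week": report.missingness.slope_per_week,
            "se": report.missingness.se,
            "p_value": report.missingness.p_value,
            "n": report.missingness.n,
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if report.comparison is not None:
        report.comparison.table.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
    log_lines = [
        f"records in: {report.selection.total}",
        f"records retained: {report.selection.retained}",
        f"fit converged: {report.results.converged} ({report.results.iterations} iterations)",
        f"modal gestation: {report.modal.week} weeks",
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
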