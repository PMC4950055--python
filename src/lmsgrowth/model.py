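"""Penalized maximum-likelihood fitting of smooth LMS curves.

The model: birth weight ``y_i`` at gestation ``t_i`` follows a BCCG
distribution with age-varying parameters — Box-Cox power ``L(t)``, median
``mu_i = M(t_i) * exp(delta * female_i)`` (log link, so ``delta`` is a
constant log-scale sex offset, i.e. a constant *percentage* difference in
the median), and coefficient of variation ``S(t)``.  ``L`` and ``S`` are
pooled across sexes.  Each curve is a cubic B-spline whose wiggliness is
controlled by a difference penalty; the penalty weight is calibrated by
bisection so the smoother has a requested effective degrees of freedom
(edf), the interpretable smoothing knob.

Estimation maximises the penalized log-likelihood

    sum_i [ L_i*log(y_i/mu_i) - log S_i - z_i^2/2 - log y_i - log(2*pi)/2 ]
      - (1/2) * sum_c lambda_c * gamma_c' P_c gamma_c

by cyclic backfitting: each curve takes one penalized Fisher-scoring step
holding the others fixed (the median block updates jointly with delta),
with step-halving whenever a step would decrease the objective, iterated to
a relative-change tolerance.  The Fisher weights per observation are
``7*S^2/4`` for L, ``1/S^2 + 2*L^2`` for log M, and ``2`` for log S.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import bccg
from ._splines import SingularBasisError, SplineBasis, difference_penalty, edf_for_lambda, lambda_for_edf
from .bccg import LMSTable, LMSTriple, CentileSpec, DEFAULT_CENTILES, make_centile_table, round_half_away

__all__ = ["FitConfig", "LMSModel", "LMSResults", "SexDifference", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    """Too few usable records (or a missing sex) for the requested fit."""


@dataclass(frozen=True)
class FitConfig:
    """Settings for an LMS curve fit.

    Attributes
    ----------
    week_range_fit : (int, int)
        Completed-week window used for fitting; records outside it are
        excluded (not clamped).
    week_range_report : (int, int)
        Window tabulated by default when evaluating the fitted curves; must
        lie inside the fit window.
    edf_L, edf_M, edf_S : float
        Effective degrees of freedom per curve; 1 means a constant.
    max_iterations : int
        Cap on outer backfitting cycles.
    tolerance : float
        Relative change in penalized log-likelihood declaring convergence.
    sex_offset : bool
        Fit the constant log-scale sex offset delta (requires both sexes).
    """

    week_range_fit: tuple[int, int] = (28, 43)
    week_range_report: tuple[int, int] = (30, 42)
    edf_L: float = 4.0
    edf_M: float = 6.0
    edf_S: float = 4.0
    max_iterations: int = 100
    tolerance: float = 1e-7
    sex_offset: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.week_range_fit
        rlo, rhi = self.week_range_report
        if lo >= hi:
            raise ValueError(f"invalid fit window {self.week_range_fit}")
        if not (lo <= rlo <= rhi <= hi):
            raise ValueError("report window must lie inside the fit window")
        for name in ("edf_L", "edf_M", "edf_S"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 (1 = constant curve)")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("tolerance must be positive and max_iterations >= 1")


# --- numerically safe BCCG building blocks (vectorised over records) -------

_NU_EPS = 1e-5


def _zscores(s: np.ndarray, sigma: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """z from s = log(y/mu): expm1-based with a series branch near nu = 0."""
    ls = nu * s
    nu_safe = np.where(np.abs(nu) < _NU_EPS, 1.0, nu)
    direct = np.expm1(ls) / (nu_safe * sigma)
    series = (s / sigma) * (1.0 + ls / 2.0 + ls * ls / 6.0)
    return np.where(np.abs(nu) < _NU_EPS, series, direct)


def _score_nu(s: np.ndarray, z: np.ndarray, sigma: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """d loglik / d nu = s - z^2*s + z*G/sigma with G = (expm1(nu*s) - nu*s)/nu^2."""
    ls = nu * s
    nu_safe = np.where(np.abs(nu) < _NU_EPS, 1.0, nu)
    G_direct = (np.expm1(ls) - ls) / (nu_safe * nu_safe)
    G_series = s * s / 2.0 + ls * s * s / 6.0 + ls * ls * s * s / 24.0
    G = np.where(np.abs(nu) < _NU_EPS, G_series, G_direct)
    return s - z * z * s + z * G / sigma


class LMSModel:
    """Age-varying BCCG model for a positive measurement.

    Parameters
    ----------
    weight : array-like of float
        Measurements in grams (positive).
    gestation : array-like
        Completed weeks (integer-valued; NaN allowed, such records drop out).
    sex : array-like of {"M", "F"}, optional
        Omit for a single-sex fit (the sex offset is then disabled).
    config : FitConfig, optional

    Records with a missing weight or gestation, or a gestation outside the
    fit window, are excluded before fitting.
    """

    def __init__(self, weight, gestation, sex=None, config: FitConfig | None = None):
        self.config = config or FitConfig()
        y = np.asarray(weight, dtype=float)
        t = np.asarray(gestation, dtype=float)
        if y.shape != t.shape:
            raise ValueError("weight and gestation must have equal length")
        if sex is not None:
            sx = np.asarray(sex, dtype=object)
            if sx.shape != y.shape:
                raise ValueError("sex must match weight length")
            bad = ~np.isin(sx, bccg.SEXES) & ~pd.isna(sx)
            if bad.any():
                raise ValueError(f"unknown sex codes: {sorted(set(sx[bad]))}")
        else:
            sx = None

        lo, hi = self.config.week_range_fit
        ok = np.isfinite(y) & np.isfinite(t) & (t >= lo) & (t <= hi)
        if sx is not None:
            ok &= ~pd.isna(sx)
        if np.any(ok & (y <= 0)):
            raise bccg.InvalidParameterError("non-positive weights in the fit window")
        self.n_excluded = int((~ok).sum())
        self.y = y[ok]
        self.t = t[ok]
        self.female = (
            (sx[ok] == "F").astype(float) if sx is not None else np.zeros(self.y.size)
        )
        self._has_both_sexes = sx is not None and 0 < self.female.mean() < 1
        self._use_delta = self.config.sex_offset and sx is not None
        if self.y.size < 50:
            raise InsufficientDataError(
                f"need >= 50 usable records in the fit window, got {self.y.size}"
            )
        if self._use_delta and not self._has_both_sexes:
            raise InsufficientDataError("sex_offset=True requires both sexes present")

        self._build_bases()

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, config: FitConfig | None = None) -> "LMSModel":
        """Build from a records table with columns sex, gest_weeks, weight_g."""
        for col in ("sex", "gest_weeks", "weight_g"):
            if col not in records.columns:
                raise ValueError(f"records are missing column {col!r}")
        return cls(
            weight=records["weight_g"].to_numpy(dtype=float),
            gestation=pd.to_numeric(records["gest_weeks"], errors="coerce").to_numpy(dtype=float),
            sex=records["sex"].to_numpy(dtype=object),
            config=config,
        )

    # -- bases ---------------------------------------------------------------

    def _build_bases(self) -> None:
        lo, hi = self.config.week_range_fit
        self._bases, self._pens, self._B = {}, {}, {}
        for name, edf in (("L", self.config.edf_L), ("M", self.config.edf_M), ("S", self.config.edf_S)):
            if edf <= 1.0 + 1e-9:
                basis = SplineBasis(lo, hi, constant=True)
                pen = np.zeros((1, 1))
            else:
                basis = SplineBasis(lo, hi)
                pen = difference_penalty(basis.k, order=2 if edf >= 2.0 else 1)
            self._bases[name] = basis
            self._pens[name] = pen
            self._B[name] = basis.design(self.t)

    # -- likelihood ----------------------------------------------------------

    def _curves(self, gL, gM, gS, delta):
        nu = self._B["L"] @ gL
        eta = self._B["M"] @ gM + delta * self.female
        sigma = np.exp(self._B["S"] @ gS)
        s = np.log(self.y) - eta
        z = _zscores(s, sigma, nu)
        return nu, sigma, s, z

    def loglike(self, gL, gM, gS, delta=0.0) -> float:
        """Unpenalized BCCG log-likelihood at the given curve coefficients."""
        nu, sigma, s, z = self._curves(gL, gM, gS, delta)
        return float(
            np.sum(nu * s - np.log(sigma) - 0.5 * z * z)
            - np.sum(np.log(self.y))
            - 0.5 * self.y.size * np.log(2.0 * np.pi)
        )

    def _penalty(self, gL, gM, gS, lams) -> float:
        return 0.5 * (
            lams["L"] * gL @ self._pens["L"] @ gL
            + lams["M"] * gM @ self._pens["M"] @ gM
            + lams["S"] * gS @ self._pens["S"] @ gS
        )

    # -- starting values -----------------------------------------------------

    def _start(self):
        cfg = self.config
        df = pd.DataFrame({"y": self.y, "t": self.t, "f": self.female})
        if self._use_delta:
            med_m = df.loc[df.f == 0, "y"].median()
            med_f = df.loc[df.f == 1, "y"].median()
            delta0 = float(np.log(med_f / med_m))
        else:
            delta0 = 0.0
        y_adj = self.y / np.exp(delta0 * self.female)
        df["ya"] = y_adj
        by_week = df.groupby("t")["ya"]
        med = by_week.median()
        iqr = by_week.quantile(0.75) - by_week.quantile(0.25)
        cv = (iqr / 1.349) / med
        global_cv = float(
            ((df["ya"].quantile(0.75) - df["ya"].quantile(0.25)) / 1.349) / df["ya"].median()
        )
        cv = cv.where(np.isfinite(cv) & (cv > 0.01), max(global_cv, 0.02))

        sigma0 = float(np.clip(global_cv, 0.02, 1.0))
        # per-record responses: the log median / log CV of the record's week
        r_m = np.log(med.reindex(self.t).to_numpy())
        r_s = np.log(cv.reindex(self.t).to_numpy())

        lams, gammas = {}, {}
        weights0 = {
            "L": np.full(self.y.size, 1.75 * sigma0 * sigma0),
            "M": np.full(self.y.size, 1.0 / sigma0**2 + 2.0),
            "S": np.full(self.y.size, 2.0),
        }
        for name, edf in (("L", cfg.edf_L), ("M", cfg.edf_M), ("S", cfg.edf_S)):
            B, P = self._B[name], self._pens[name]
            if self._bases[name].constant:
                lams[name] = 0.0
                continue
            btwb = B.T @ (weights0[name][:, None] * B)
            lams[name] = lambda_for_edf(btwb, P, edf)
        for name, r in (("M", r_m), ("S", r_s)):
            B, P = self._B[name], self._pens[name]
            w = weights0[name]
            A = B.T @ (w[:, None] * B) + lams[name] * P
            gammas[name] = np.linalg.solve(A, B.T @ (w * r))
        gammas["L"] = self._bases["L"].constant_coefs(1.0)
        if self._bases["M"].constant:
            gammas["M"] = np.array([float(np.average(r_m))])
        if self._bases["S"].constant:
            gammas["S"] = np.array([float(np.average(r_s))])
        return gammas["L"], gammas["M"], gammas["S"], delta0, lams

    # -- fitting -------------------------------------------------------------

    def fit(self) -> "LMSResults":
        """Run the backfitting loop and return an :class:`LMSResults`."""
        cfg = self.config
        gL, gM, gS, delta, lams = self._start()
        penll = self.loglike(gL, gM, gS, delta) - self._penalty(gL, gM, gS, lams)
        trace = [penll]
        converged = False
        it = 0
        for it in range(1, cfg.max_iterations + 1):
            gM, delta, penll = self._step_M(gL, gM, gS, delta, lams, penll)
            gS, penll = self._step_curve("S", gL, gM, gS, delta, lams, penll)
            gL, penll = self._step_curve("L", gL, gM, gS, delta, lams, penll)
            trace.append(penll)
            if abs(trace[-1] - trace[-2]) <= cfg.tolerance * (abs(trace[-2]) + 1.0):
                converged = True
                break

        nu, sigma, s, z = self._curves(gL, gM, gS, delta)
        delta_se = self._delta_se(gL, gM, gS, delta, lams) if self._use_delta else None
        edf_achieved = {}
        final_w = {
            "L": 1.75 * sigma * sigma,
            "M": 1.0 / sigma**2 + 2.0 * nu * nu,
            "S": np.full(self.y.size, 2.0),
        }
        for name in ("L", "M", "S"):
            if self._bases[name].constant:
                edf_achieved[name] = 1.0
            else:
                B = self._B[name]
                btwb = B.T @ (final_w[name][:, None] * B)
                edf_achieved[name] = edf_for_lambda(btwb, self._pens[name], lams[name])
        return LMSResults(
            model=self,
            gL=gL,
            gM=gM,
            gS=gS,
            delta=float(delta),
            delta_se=delta_se,
            converged=converged,
            iterations=it,
            llf=self.loglike(gL, gM, gS, delta),
            llf_penalized=penll,
            trace=np.asarray(trace),
            pen_lambda=dict(lams),
            edf=edf_achieved,
            zscores=z,
        )

    def _accept(self, old_penll, candidate_penll_fn, apply_full, apply_frac):
        """Step-halving: accept the largest fraction not decreasing the objective."""
        frac = 1.0
        for _ in range(25):
            pll = candidate_penll_fn(frac)
            if pll >= old_penll - 1e-12 * (abs(old_penll) + 1.0):
                return frac, pll
            frac *= 0.5
        return 0.0, old_penll

    def _step_M(self, gL, gM, gS, delta, lams, penll):
        nu, sigma, s, z = self._curves(gL, gM, gS, delta)
        u = z / sigma + nu * (z * z - 1.0)
        w = 1.0 / sigma**2 + 2.0 * nu * nu
        B = self._B["M"]
        if self._use_delta:
            X = np.column_stack([B, self.female])
            P = np.zeros((X.shape[1], X.shape[1]))
            P[:-1, :-1] = lams["M"] * self._pens["M"]
            theta = np.append(gM, delta)
        else:
            X = B
            P = lams["M"] * self._pens["M"]
            theta = gM.copy()
        A = X.T @ (w[:, None] * X) + P
        rhs = X.T @ u - P @ theta
        step = np.linalg.solve(A, rhs)

        def pll_at(frac):
            th = theta + frac * step
            if self._use_delta:
                g, d = th[:-1], th[-1]
            else:
                g, d = th, delta
            return self.loglike(gL, g, gS, d) - self._penalty(gL, g, gS, lams)

        frac, new_pll = self._accept(penll, pll_at, None, None)
        th = theta + frac * step
        if self._use_delta:
            return th[:-1], float(th[-1]), new_pll
        return th, delta, new_pll

    def _step_curve(self, name, gL, gM, gS, delta, lams, penll):
        nu, sigma, s, z = self._curves(gL, gM, gS, delta)
        if name == "S":
            u = z * z - 1.0
            w = np.full(self.y.size, 2.0)
            theta = gS.copy()
        else:
            u = _score_nu(s, z, sigma, nu)
            w = 1.75 * sigma * sigma
            theta = gL.copy()
        B = self._B[name]
        P = lams[name] * self._pens[name]
        A = B.T @ (w[:, None] * B) + P
        step = np.linalg.solve(A, B.T @ u - P @ theta)

        def pll_at(frac):
            th = theta + frac * step
            args = (gL, gM, th, delta) if name == "S" else (th, gM, gS, delta)
            return self.loglike(*args) - self._penalty(args[0], args[1], args[2], lams)

        frac, new_pll = self._accept(penll, pll_at, None, None)
        return theta + frac * step, new_pll

    def _delta_se(self, gL, gM, gS, delta, lams) -> float:
        """SE of delta from the penalized Fisher information of the (M, delta) block."""
        nu, sigma, s, z = self._curves(gL, gM, gS, delta)
        w = 1.0 / sigma**2 + 2.0 * nu * nu
        X = np.column_stack([self._B["M"], self.female])
        P = np.zeros((X.shape[1], X.shape[1]))
        P[:-1, :-1] = lams["M"] * self._pens["M"]
        cov = np.linalg.inv(X.T @ (w[:, None] * X) + P)
        return float(np.sqrt(cov[-1, -1]))


@dataclass(frozen=True)
class SexDifference:
    """Percentage by which the girls' median lies below the boys' (with 95% CI)."""

    percent: float
    ci_lower: float
    ci_upper: float


@dataclass
class LMSResults:
    """Fitted LMS curves plus diagnostics; produced by :meth:`LMSModel.fit`."""

    model: LMSModel
    gL: np.ndarray
    gM: np.ndarray
    gS: np.ndarray
    delta: float
    delta_se: float | None
    converged: bool
    iterations: int
    llf: float
    llf_penalized: float
    trace: np.ndarray
    pen_lambda: dict
    edf: dict
    zscores: np.ndarray

    # -- evaluation ----------------------------------------------------------

    def curves_at(self, t, sex: str = "M"):
        """(L, M, S) curve values at gestations ``t`` (within the fit window)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.model.config.week_range_fit
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"gestation outside the fit window {lo}..{hi}")
        female = 1.0 if sex == "F" else 0.0
        if sex not in bccg.SEXES:
            raise ValueError(f"unknown sex code {sex!r}")
        bL = self.model._bases["L"].design(t) @ self.gL
        m = np.exp(self.model._bases["M"].design(t) @ self.gM + self.delta * female)
        sg = np.exp(self.model._bases["S"].design(t) @ self.gS)
        return bL, m, sg

    def triple(self, sex: str, t: float) -> LMSTriple:
        L, M, S = self.curves_at(t, sex)
        return LMSTriple(float(L[0]), float(M[0]), float(S[0]))

    def zscore(self, weight, gestation, sex="M") -> np.ndarray:
        """SD scores of new measurements under the fitted curves."""
        weight = np.atleast_1d(np.asarray(weight, dtype=float))
        gestation = np.atleast_1d(np.asarray(gestation, dtype=float))
        if np.isscalar(sex) or isinstance(sex, str):
            sex = np.full(weight.shape, sex, dtype=object)
        else:
            sex = np.asarray(sex, dtype=object)
        out = np.empty(weight.shape)
        for code in ("M", "F"):
            mask = sex == code
            if not mask.any():
                continue
            L, M, S = self.curves_at(gestation[mask], code)
            s = np.log(weight[mask] / M)
            out[mask] = _zscores(s, S, L)
        return out

    def lms_table(
        self,
        weeks: Sequence[int] | None = None,
        round_params: bool = True,
        decimals: tuple[int, int] = (2, 3),
    ) -> LMSTable:
        """Tabulate the fitted curves at integer weeks as an :class:`LMSTable`.

        Defaults to the report window.  With ``round_params`` the median is
        rounded to integer grams, L to ``decimals[0]`` and S to
        ``decimals[1]`` places (chart-publication precision).
        """
        if weeks is None:
            lo, hi = self.model.config.week_range_report
            weeks = range(lo, hi + 1)
        sexes = ("M", "F") if self.model._use_delta or self.model._has_both_sexes else ("M",)
        rows = []
        for sex in sexes:
            L, M, S = self.curves_at(np.asarray(list(weeks), float), sex)
            for w, l, m, s in zip(weeks, L, M, S):
                if round_params:
                    l, m, s = round(l, decimals[0]), round_half_away(m), round(s, decimals[1])
                rows.append({"sex": sex, "week": int(w), "L": l, "M": m, "S": s})
        return LMSTable(pd.DataFrame(rows))

    def centile_table(self, spec: CentileSpec = DEFAULT_CENTILES, weeks=None):
        """Centile chart from the fitted (unrounded) curves."""
        return make_centile_table(self.lms_table(weeks=weeks, round_params=False), spec)

    # -- summaries -----------------------------------------------------------

    def sex_difference_percent(self) -> SexDifference:
        """100*(1 - exp(delta)) with a normal-theory 95% CI."""
        if not self.model._use_delta:
            raise ValueError("model was fitted without a sex offset")
        lo = self.delta + 1.96 * self.delta_se
        hi = self.delta - 1.96 * self.delta_se
        return SexDifference(
            percent=100.0 * (1.0 - np.exp(self.delta)),
            ci_lower=100.0 * (1.0 - np.exp(lo)),
            ci_upper=100.0 * (1.0 - np.exp(hi)),
        )

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "LMS (BCCG) penalized-likelihood fit",
            "=" * 44,
            f"records used          {self.model.y.size}"
            + (f"  (excluded {self.model.n_excluded})" if self.model.n_excluded else ""),
            f"fit window (weeks)    {cfg.week_range_fit[0]}-{cfg.week_range_fit[1]}",
            f"converged             {self.converged} in {self.iterations} iterations",
            f"log-likelihood        {self.llf:.2f} (penalized {self.llf_penalized:.2f})",
            "edf (target -> used)  "
            + ", ".join(
                f"{n}: {getattr(cfg, 'edf_' + n):.3g} -> {self.edf[n]:.2f}" for n in ("L", "M", "S")
            ),
            f"z-scores              mean {self.zscores.mean():+.4f}, SD {self.zscores.std(ddof=1):.4f}",
        ]
        if self.model._use_delta:
            sd = self.sex_difference_percent()
            lines.append(
                f"sex offset delta      {self.delta:+.5f} (SE {self.delta_se:.5f})"
            )
            lines.append(
                f"girls below boys      {sd.percent:.1f}% (95% CI {sd.ci_lower:.1f}-{sd.ci_upper:.1f})"
            )
        return "\n".join(lines)

    def diagnostics(self) -> dict:
        """JSON-ready fit diagnostics block."""
        out = {
            "n_records": int(self.model.y.size),
            "n_excluded": int(self.model.n_excluded),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "loglik": float(self.llf),
            "penalized_loglik": float(self.llf_penalized),
            "edf": {k: float(v) for k, v in self.edf.items()},
            "zscore_mean": float(self.zscores.mean()),
            "zscore_sd": float(self.zscores.std(ddof=1)),
        }
        if self.model._use_delta:
            sd = self.sex_difference_percent()
            out["delta"] = float(self.delta)
            out["delta_se"] = float(self.delta_se)
            out["sex_difference_percent"] = float(sd.percent)
            out["sex_difference_ci"] = [float(sd.ci_lower), float(sd.ci_upper)]
        return out

    def plot_centiles(self, spec: CentileSpec = DEFAULT_CENTILES, sex: str = "M", ax=None):
        """Plot fitted centile curves for one sex on fine gestation grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.model.config.week_range_report
        tt = np.linspace(lo, hi, 200)
        L, M, S = self.curves_at(tt, sex)
        for label, z in spec:
            vals = [bccg.centile_value(LMSTriple(l, m, s), z) for l, m, s in zip(L, M, S)]
            ax.plot(tt, vals, label=label, lw=1)
        ax.set_xlabel("gestational age (completed weeks)")
        ax.set_ylabel("birth weight (g)")
        ax.legend(fontsize="small")
        return ax
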