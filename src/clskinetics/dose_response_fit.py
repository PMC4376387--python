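"""Dose-response fitting and parameter-plot construction.

Per assay cell (one reporter and cofactor dose), the steroid dose-response

    A(S) = (A_max + (A_min/IC50)*S) / (1 + S/IC50)

is fit by the two-stage recipe: ``A_max`` is the mean activity at zero
steroid; the remaining points, subtracted from ``A_max``, are fit to a
saturating (Michaelis-Menten) function yielding ``A_min`` and ``IC50``.
The fitted parameters are normalized to the lowest reporter+cofactor cell,
averaged across experiments, and plotted versus cofactor (or reporter)
amount; those parameter plots are themselves fit by linear-fractional
curves and reduced to a qualitative :class:`~clskinetics.classification.PlotSignature`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .classification import PlotSignature
from .config_formulas import lf_shape
from .kinetic_core import LinearFractional

__all__ = [
    "DRParamEstimate",
    "WesternCalibration",
    "ParamPlotDataset",
    "ParamFit",
    "eq1_activity",
    "fit_dose_response",
    "fit_grid",
    "normalize_grid",
    "western_linearize",
    "fit_param_vs_cofactor",
    "extract_signature",
]

ASSAY_COLUMNS = [
    "reporter_dose",
    "cofactor_id",
    "cofactor_dose",
    "steroid_dose",
    "replicate",
    "activity",
]

PARAM_NAMES = ("amax", "amin", "ic50", "ratio")


def eq1_activity(S, amax, amin, ic50):
    """Repression dose-response: ``(amax + amin*S/ic50) / (1 + S/ic50)``."""
    S = np.asarray(S, dtype=float)
    return (amax + amin * S / ic50) / (1.0 + S / ic50)


@dataclass
class DRParamEstimate:
    """Fitted dose-response parameters of one assay cell."""

    amax: float
    amin: float
    ic50: float
    r_squared: float
    amin_se: float = np.nan
    ic50_se: float = np.nan
    ec50: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def ratio(self) -> float:
        if not self.amin > 0:
            return np.nan
        return self.amax * self.ic50 / self.amin


@dataclass(frozen=True)
class WesternCalibration:
    """Saturating blot-intensity calibration OD = m1*p/(m2+p)."""

    m1: float
    m2: float

    def __post_init__(self):
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("m1, m2 must be > 0")

    def linearize(self, plasmid):
        p = np.asarray(plasmid, dtype=float)
        return self.m2 * p / (self.m2 + p)


def fit_dose_response(
    doses: Sequence[float],
    activities: Sequence[float],
    mode: str = "repression",
    joint: bool = False,
) -> DRParamEstimate:
    """Two-stage fit of the repression dose-response.

    ``A_max`` is the mean of the zero-dose activities; the zero-subtracted
    curve is then fit to ``(A_max - A_min) * S / (IC50 + S)`` by least
    squares.  ``joint=True`` instead fits all three parameters
    simultaneously (available for comparison).  R^2 is reported for the
    full curve against every point.
    """
    S = np.asarray(doses, dtype=float)
    A = np.asarray(activities, dtype=float)
    if S.shape != A.shape:
        raise ValueError("doses and activities must align")
    zero = S == 0
    if not zero.any():
        raise ValueError("need at least one zero-steroid (vehicle) point")
    if (~zero).sum() < 3 or len(np.unique(S[~zero])) < 3:
        raise ValueError("need >= 3 distinct positive steroid doses")
    flags: list[str] = []
    amax = float(A[zero].mean())

    Sp, Ap = S[~zero], A[~zero]
    span = A.max() - A.min()
    if span <= 1e-12 * max(abs(A).max(), 1.0):
        return DRParamEstimate(
            amax=amax, amin=amax, ic50=np.nan, r_squared=1.0,
            flags=["flat: IC50 undefined"],
        )
    # group means per dose to sniff the direction
    order = np.argsort(Sp)
    if mode == "repression" and Ap[order][-3:].mean() > amax + 0.05 * span:
        flags.append("activity increases with dose: wrong mode?")

    if joint:
        p0 = [amax, max(Ap.min(), 1e-12), np.median(Sp)]
        popt, pcov = curve_fit(
            eq1_activity, S, A, p0=p0,
            bounds=([0, 0, 1e-12], [np.inf] * 3), maxfev=20000,
        )
        amax, amin, ic50 = (float(v) for v in popt)
        amin_se, ic50_se = (float(np.sqrt(pcov[i, i])) for i in (1, 2))
    else:
        delta = amax - Ap

        def mm(S, dmax, ic50):
            return dmax * S / (ic50 + S)

        # A_min >= 0 enforces dmax <= A_max; IC50 is kept within a generous
        # window of the dosed range (unidentifiable midpoints otherwise run
        # away and poison downstream normalization)
        ic_lo, ic_hi = Sp.min() / 30.0, Sp.max() * 30.0
        p0 = [
            float(np.clip(delta.max(), 1e-9 * max(amax, 1e-30), max(amax, 1e-12))),
            float(np.clip(np.median(Sp), ic_lo, ic_hi)),
        ]
        popt, pcov = curve_fit(
            mm, Sp, delta, p0=p0,
            bounds=([0.0, ic_lo], [max(amax, 1e-12), ic_hi]), maxfev=20000,
        )
        dmax, ic50 = (float(v) for v in popt)
        amin = amax - dmax
        amin_se = float(np.sqrt(pcov[0, 0]))
        ic50_se = float(np.sqrt(pcov[1, 1]))
    if amin < 0:
        flags.append("negative fitted A_min clipped to 0")
        amin = 0.0
    # a nearly flat curve has no identifiable midpoint: report the plateaus
    # but leave IC50 (and hence the ratio) undefined
    depth = (amax - amin) / amax if amax > 0 else 0.0
    if depth < 0.20 or ic50 >= 0.99 * (S[S > 0].max() * 30.0):
        flags.append("repression too shallow: IC50 unidentifiable")
        ic50 = np.nan
    pred = eq1_activity(S, amax, amin, ic50 if np.isfinite(ic50) else np.inf)
    ss_res = float(np.sum((A - pred) ** 2))
    ss_tot = float(np.sum((A - A.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DRParamEstimate(
        amax=amax, amin=amin, ic50=ic50, r_squared=r2,
        amin_se=amin_se, ic50_se=ic50_se, flags=flags,
    )


# ---------------------------------------------------------------------------
# grids and parameter plots
# ---------------------------------------------------------------------------


def fit_grid(table: pd.DataFrame, mode: str = "repression") -> pd.DataFrame:
    """Fit every (experiment, reporter, cofactor) cell of an assay table."""
    df = table.copy()
    if "experiment" not in df.columns:
        df["experiment"] = 0
    rows = []
    for (exp, rep, cof), g in df.groupby(
        ["experiment", "reporter_dose", "cofactor_dose"]
    ):
        est = fit_dose_response(
            g["steroid_dose"].to_numpy(), g["activity"].to_numpy(), mode=mode
        )
        rows.append(
            {
                "experiment": exp,
                "reporter_dose": rep,
                "cofactor_dose": cof,
                "amax": est.amax,
                "amin": est.amin,
                "ic50": est.ic50,
                "ratio": est.ratio,
                "r_squared": est.r_squared,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ParamPlotDataset:
    """Normalized parameter series vs cofactor (or reporter) amount.

    ``x`` holds *total* amounts (exogenous dose + endogenous level) in
    strictly increasing order; each series carries per-point SEMs (NaN when
    only one contributing value).
    """

    x: np.ndarray
    series: dict[str, tuple[np.ndarray, np.ndarray]]
    n: np.ndarray
    mode: str = "cofactor"
    endogenous: float = 0.0
    reporter_level: float = 1.0

    def __post_init__(self):
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        data = {"x": self.x, "n": self.n}
        for k, (m, s) in self.series.items():
            data[k] = m
            data[k + "_sem"] = s
        return pd.DataFrame(data)


def normalize_grid(
    table: pd.DataFrame,
    mode: str = "cofactor",
    endogenous: float = 0.0,
    dr_mode: str = "repression",
    anchor: str = "trace",
) -> ParamPlotDataset:
    """Build normalized dose-response-parameter plots from an assay table.

    ``anchor='global'`` divides every fitted parameter by its value in the
    lowest-reporter, lowest-cofactor cell of the same experiment (the
    verbatim published recipe).  ``anchor='trace'`` (default) instead
    anchors each experiment x off-axis-level trace at its own lowest
    x point before averaging: because the CLS accelerator enters the
    activity linearly, the parameter surfaces are separable in reporter
    and cofactor, so this yields the same normalized curve while keeping
    the SEMs free of between-trace scale variance.  ``mode`` selects the
    x axis ('cofactor' or 'reporter'); the endogenous level is added to
    the x values so the axis reflects total amounts.
    """
    params = fit_grid(table, mode=dr_mode)
    lo_rep = params["reporter_dose"].min()
    lo_cof = params["cofactor_dose"].min()
    xcol = "cofactor_dose" if mode == "cofactor" else "reporter_dose"
    ocol = "reporter_dose" if mode == "cofactor" else "cofactor_dose"
    lo_x = lo_cof if mode == "cofactor" else lo_rep
    norm_parts = []
    if anchor == "global":
        group_cols = ["experiment"]
        anchor_mask = lambda g: (g["reporter_dose"] == lo_rep) & (
            g["cofactor_dose"] == lo_cof
        )
    elif anchor == "trace":
        group_cols = ["experiment", ocol]
        anchor_mask = lambda g: g[xcol] == lo_x
    else:
        raise ValueError("anchor must be 'global' or 'trace'")
    # IC50 and the ratio live on the dose axis: the CLS accelerator scale
    # and any per-experiment activity scale cancel out of them exactly, so
    # in 'trace' mode they are aggregated raw; only the activity-scale
    # parameters A_max and A_min need anchoring.
    scaled = PARAM_NAMES if anchor == "global" else ("amax", "amin")
    for key, g in params.groupby(group_cols):
        a_rows = g[anchor_mask(g)]
        if a_rows.empty:
            raise ValueError(
                f"group {key}: missing anchor cell "
                f"(reporter {lo_rep}, cofactor {lo_cof})"
            )
        a = a_rows.iloc[0]
        gg = g.copy()
        for p in scaled:
            # trace mode scales both activity parameters by the anchor
            # A_max so the A_max > A_min relation survives normalization
            av = a["amax"] if (anchor == "trace" and p == "amin") else a[p]
            gg[p] = gg[p] / av if np.isfinite(av) and av > 0 else np.nan
        norm_parts.append(gg)
    norm = pd.concat(norm_parts, ignore_index=True)

    xcol = "cofactor_dose" if mode == "cofactor" else "reporter_dose"
    grouped = norm.groupby(xcol)
    x = np.array(sorted(grouped.groups))
    series = {}
    counts = grouped.size().reindex(x).to_numpy()
    for p in PARAM_NAMES:
        mean = grouped[p].mean().reindex(x).to_numpy()
        n = grouped[p].count().reindex(x).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sd = grouped[p].std(ddof=1).reindex(x).to_numpy()
        sem = np.where(n > 1, sd / np.sqrt(n), np.nan)
        series[p] = (mean, sem)
    return ParamPlotDataset(
        x=x + endogenous,
        series=series,
        n=counts,
        mode=mode,
        endogenous=endogenous,
        reporter_level=float(lo_rep) if mode == "cofactor" else 1.0,
    )


# ---------------------------------------------------------------------------
# Western-blot linearization
# ---------------------------------------------------------------------------


def western_linearize(
    od: Sequence[float], plasmid: Sequence[float]
) -> tuple[WesternCalibration, np.ndarray]:
    """Correct transfected-plasmid amounts for saturating protein expression.

    Fits ``OD = m1*p/(m2+p)`` and returns the calibration plus the
    linear-equivalent amounts ``m2*p/(m2+p)``.  When the data show no
    curvature (m2 unidentifiable) the identity correction is returned with
    a warning.
    """
    od = np.asarray(od, dtype=float)
    p = np.asarray(plasmid, dtype=float)
    if len(p) < 3:
        raise ValueError("need >= 3 plasmid levels")

    def sat(p, m1, m2):
        return m1 * p / (m2 + p)

    try:
        popt, pcov = curve_fit(
            sat, p, od, p0=[od.max() * 2 or 1.0, np.median(p[p > 0])],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("western calibration failed; returning identity correction")
        return WesternCalibration(m1=1.0, m2=np.inf if False else 1e12), p.copy()
    m1, m2 = (float(v) for v in popt)
    m2_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    if m2 > 10 * p.max() or m2_se > 0.5 * m2:
        warnings.warn(
            "no detectable curvature: m2 unidentifiable, identity correction"
        )
        return WesternCalibration(m1=m1, m2=m2), p.copy()
    cal = WesternCalibration(m1=m1, m2=m2)
    return cal, cal.linearize(p)


# ---------------------------------------------------------------------------
# parameter-plot fits
# ---------------------------------------------------------------------------


@dataclass
class ParamFit:
    """Weighted linear-fractional fit of one parameter plot."""

    lf: LinearFractional
    best_shape: str                 # 'const' | 'linear' | 'mm' | 'lf'
    bic: dict[str, float]
    chi2: dict[str, float]
    x_intercept: float
    x_intercept_se: float
    weighted: bool
    shape_params: dict[str, tuple] = field(default_factory=dict)


def _shape_models():
    return {
        "const": (lambda x, a: np.full_like(np.asarray(x, float), a), 1),
        "linear": (lambda x, b: b * np.asarray(x, float), 1),
        "mm": (lambda x, b, d: b * np.asarray(x, float) / (1.0 + d * x), 2),
        "lf": (lambda x, a, b, d: (a + b * np.asarray(x, float)) / (1.0 + d * x), 3),
    }


def fit_param_vs_cofactor(
    x: Sequence[float],
    y: Sequence[float],
    sem: Sequence[float] | None = None,
) -> ParamFit:
    """Weighted least-squares fit of ``y = (a + b x)/(1 + d x)`` plus nulls.

    Nested null shapes (constant, linear through origin, Michaelis-Menten)
    are fit alongside and ranked by BIC = chi^2 + k ln n.  Weights are
    1/sem^2; an unweighted fit is used when SEMs are missing/non-finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sem = None if sem is None else np.asarray(sem, dtype=float)
    keep = np.isfinite(y)
    if sem is not None:
        # points with no usable uncertainty cannot be weighted against the
        # rest; drop them unless nothing carries a finite SEM at all
        if np.any(np.isfinite(sem) & keep):
            keep &= np.isfinite(sem)
        else:
            sem = None
    if keep.sum() < 2:
        raise ValueError("need >= 2 finite points")
    x, y = x[keep], y[keep]
    if sem is not None:
        sem = sem[keep]
    n = len(x)
    weighted = sem is not None and np.any(sem > 0)
    if weighted:
        floor = 0.5 * sem[sem > 0].min()
        sigma = np.maximum(sem, floor)  # exact (anchor) points get a tight floor
    else:
        sigma = np.full(n, max(np.std(y), 1e-12))

    chi2: dict[str, float] = {}
    bic: dict[str, float] = {}
    fits: dict[str, tuple] = {}
    yscale = max(abs(y).max(), 1e-12)
    xmed = np.median(x[x > 0]) if (x > 0).any() else 1.0
    p0s = {
        "const": [float(np.mean(y))],
        "linear": [float(yscale / max(x.max(), 1e-12))],
        "mm": [float(yscale / xmed), 1.0 / xmed],
        "lf": [float(max(y[0], 1e-9 * yscale)), float(yscale / xmed), 1.0 / xmed],
    }
    for name, (model, k) in _shape_models().items():
        if n < k + 1:
            continue
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=p0s[name], sigma=sigma, absolute_sigma=weighted,
                bounds=(0.0, np.inf), maxfev=50000,
            )
        except RuntimeError:
            continue
        resid = (y - model(x, *popt)) / sigma
        chi2[name] = float(np.sum(resid**2))
        bic[name] = chi2[name] + k * np.log(n)
        fits[name] = (popt, pcov)
    if "lf" not in fits:
        # fall back: promote the best restricted shape to LF coefficients
        best = min(bic, key=bic.get)
        popt, pcov = fits[best]
        lfc = _shape_to_lf(best, popt)
        return ParamFit(
            lf=lfc, best_shape=best, bic=bic, chi2=chi2,
            x_intercept=np.nan, x_intercept_se=np.nan, weighted=weighted,
            shape_params={k: v[0] for k, v in fits.items()},
        )
    best = min(bic, key=bic.get)
    a, b, d = fits["lf"][0]
    pcov = fits["lf"][1]
    lfc = LinearFractional(float(a), float(b), 1.0, float(d))
    # x-axis intersection of the numerator a + b x
    if b > 0:
        xi = -a / b
        # delta method: var(a/b) = (1/b)^2 var(a) + (a/b^2)^2 var(b) - 2 a/b^3 cov
        va, vb, cab = pcov[0, 0], pcov[1, 1], pcov[0, 1]
        xi_se = float(
            np.sqrt(
                max(va / b**2 + (a**2 / b**4) * vb - 2 * (a / b**3) * cab, 0.0)
            )
        )
    else:
        xi, xi_se = np.nan, np.nan
    return ParamFit(
        lf=lfc, best_shape=best, bic=bic, chi2=chi2,
        x_intercept=float(xi), x_intercept_se=xi_se, weighted=weighted,
        shape_params={k: tuple(v[0]) for k, v in fits.items()},
    )


def fit_all_params(ds: ParamPlotDataset) -> dict[str, "ParamFit | None"]:
    """Fit all four parameter plots; unfittable series map to None."""
    out: dict[str, ParamFit | None] = {}
    for p in PARAM_NAMES:
        m, s = ds.series[p]
        try:
            out[p] = fit_param_vs_cofactor(ds.x, m, s)
        except (ValueError, RuntimeError):
            out[p] = None
    return out


def _shape_to_lf(shape: str, popt) -> LinearFractional:
    if shape == "const":
        return LinearFractional(float(popt[0]), 0.0, 1.0, 0.0)
    if shape == "linear":
        return LinearFractional(0.0, float(popt[0]), 1.0, 0.0)
    if shape == "mm":
        return LinearFractional(0.0, float(popt[0]), 1.0, float(popt[1]))
    raise ValueError(shape)


# ---------------------------------------------------------------------------
# qualitative signature
# ---------------------------------------------------------------------------


def extract_signature(
    fits: Mapping[str, ParamFit],
    endogenous_level: float = 0.0,
    x_range: tuple[float, float] | None = None,
    const_tol: float = 0.05,
    ordering_tol: float = 0.25,
) -> PlotSignature:
    """Reduce the four parameter-plot fits to a qualitative signature.

    Emits per-parameter directions, linear-through-origin and
    positive-at-true-zero flags for A_max/A_min, and the half-max
    orderings.  x values are assumed to be total amounts, so the true zero
    of the factor is x = 0.  Orderings are reported only when both
    half-max concentrations are identifiable (finite, positive and within
    a decade of the data range).
    """
    missing = [p for p in PARAM_NAMES if p not in fits]
    if missing:
        raise ValueError(f"missing parameter fits: {missing}")
    directions = {}
    shapes = {}
    for p in PARAM_NAMES:
        f = fits[p]
        if f is None:  # unfittable series (e.g. IC50 undefined everywhere)
            directions[p] = None
            continue
        sh = lf_shape(f.lf, x_range=x_range, const_tol=const_tol)
        # data-driven direction: a trend is only called when the constant
        # shape is rejected decisively (delta-chi2 ~ 3.5 sigma) AND the
        # fitted change over the data range is substantial; anything weaker
        # reads as 'const', which downstream stages treat as non-informative
        xr = x_range if x_range is not None else (0.0, 1.0)
        y_lo, y_hi = f.lf(xr[0]), f.lf(xr[1])
        rel = (y_hi - y_lo) / max(abs(y_lo), abs(y_hi), 1e-300)
        dchi = f.chi2.get("const", np.inf) - min(f.chi2.values())
        if dchi <= 12.0 or abs(rel) < 0.15:
            directions[p] = "const"
        else:
            directions[p] = "inc" if rel > 0 else "dec"
        if p in ("amax", "amin"):
            linear_pref = f.bic.get("linear", np.inf) < f.bic.get("mm", np.inf) and \
                f.bic.get("linear", np.inf) <= f.bic.get("lf", np.inf) + 2.0
            origin_ok = (
                np.isfinite(f.x_intercept)
                and abs(f.x_intercept) <= 2.0 * (f.x_intercept_se or 0.0) + 1e-9
            ) or f.best_shape == "linear"
            shapes[f"{p}_linear_origin"] = bool(linear_pref and origin_ok)
            shapes[f"{p}_nonlinear"] = f.best_shape in ("mm", "lf")
            shapes[f"{p}_nonlinear_origin"] = bool(
                f.best_shape == "mm" and sh.direction == "inc"
            )
            # positive at the true zero of the factor: the fitted curve must
            # cross zero at significantly negative x (x axis already holds
            # total = dose + endogenous, so true zero is x = 0)
            se = f.x_intercept_se if np.isfinite(f.x_intercept_se) else 0.0
            shapes[f"{p}_positive_true_zero"] = bool(
                f.lf(0.0) > 0
                and np.isfinite(f.x_intercept)
                and f.x_intercept < -2.0 * se
            )
            if sh.direction == "dec":
                lim = f.lf.b / f.lf.d if f.lf.d > 0 else np.nan
                shapes[f"{p}_positive_limit"] = bool(np.isfinite(lim) and lim > 0.05 * f.lf(0.0))
                shapes[f"{p}_approaches_zero"] = bool(
                    np.isfinite(lim) and lim <= 0.05 * max(f.lf(0.0), 1e-300)
                )

    def _h(f: ParamFit, recip: bool) -> float:
        lf = f.lf
        h = (lf.a / lf.b) if recip else (lf.c / lf.d)
        return float(h) if np.isfinite(h) and h > 0 else np.nan

    def _order(h1, h2) -> str:
        if not (np.isfinite(h1) and np.isfinite(h2)):
            return "unknown"
        if x_range is not None:
            lo, hi = min(x_range) / 10 or 1e-12, max(x_range) * 10
            if not (lo <= h1 <= hi and lo <= h2 <= hi):
                return "unknown"
        if abs(h1 - h2) <= ordering_tol * max(h1, h2):
            return "="
        return "<" if h1 < h2 else ">"

    if fits["amax"] is not None and fits["amin"] is not None:
        h_order = _order(_h(fits["amin"], False), _h(fits["amax"], False))
        hr_order = _order(_h(fits["amin"], True), _h(fits["amax"], True))
        x0 = x_range[0] if x_range else 0.0
        amax_gt_amin = bool(fits["amax"].lf(x0) > fits["amin"].lf(x0))
    else:
        h_order = hr_order = "unknown"
        amax_gt_amin = None
    return PlotSignature(
        directions=directions,
        shapes=shapes,
        h_amin_vs_amax=h_order,
        h_recip_amin_vs_amax=hr_order,
        amax_gt_amin=amax_gt_amin,
    )
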