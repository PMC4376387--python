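"""Metropolis-Hastings fitting and BIC comparison of parameter-plot models.

Three model structures tie the four dose-response-parameter plots
(A_max, A_min, IC50, A_max*IC50/A_min) to the cofactor amount [X] with the
reporter level [R] as a known scale:

* predicted — the theory's structure: the four curves share numerator and
  denominator roots pairwise (8 free parameters);
* permuted — same complexity, roots deliberately mis-wired (8 parameters);
* unconstrained — independent linear-fractional curves (12 parameters);
  the predicted model is nested inside it.

Fitting maximizes ``exp(-chi^2/2)`` over log-parameters with flat priors
via a random-walk Metropolis-Hastings sampler (numba-compiled), and models
are ranked by ``BIC = chi^2_min + k ln n``.

The fourth printed equation of each model set is labelled like a second
A_max in the source material, but the compatibility structure identifies it
as the combination A_max*IC50/A_min; it is implemented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .dose_response_fit import PARAM_NAMES, ParamPlotDataset

__all__ = [
    "ModelSpec",
    "MCMCChain",
    "FitReport",
    "get_model",
    "MODELS",
    "chi_squared",
    "mh_sample",
    "model_compare",
    "posterior_halfmax_ordering",
    "split_rhat",
]

_MODEL_IDS = {"predicted": 0, "permuted": 1, "unconstrained": 2}

LOG_LO, LOG_HI = np.log(1e-4), np.log(1e4)


# ---------------------------------------------------------------------------
# model structures
# ---------------------------------------------------------------------------


def _predict_predicted(a, x, R):
    return np.stack(
        [
            a[4] * R * (a[0] + x) / (a[1] + x),
            a[5] * R * (a[2] + x) / (a[3] + x),
            a[6] * (a[1] + x) / (a[3] + x),
            a[7] * (a[0] + x) / (a[2] + x),
        ]
    )


def _predict_permuted(b, x, R):
    return np.stack(
        [
            b[4] * R * (b[0] + x) / (b[3] + x),
            b[5] * R * (b[1] + x) / (b[2] + x),
            b[6] * (b[2] + x) / (b[1] + x),
            b[7] * (b[3] + x) / (b[0] + x),
        ]
    )


def _predict_unconstrained(c, x, R):
    return np.stack(
        [
            c[8] * R * (c[0] + x) / (c[4] + x),
            c[9] * R * (c[1] + x) / (c[5] + x),
            c[10] * (c[2] + x) / (c[6] + x),
            c[11] * (c[3] + x) / (c[7] + x),
        ]
    )


@dataclass(frozen=True)
class ModelSpec:
    """One of the three comparison models."""

    id: str
    k: int
    param_names: tuple[str, ...]
    _predict: Callable = field(repr=False, compare=False)

    def predict(self, params: np.ndarray, x: np.ndarray, R: float) -> np.ndarray:
        """(4, n) array of the four parameter series at cofactor amounts x."""
        params = np.asarray(params, dtype=float)
        if params.size != self.k:
            raise ValueError(f"{self.id} model needs {self.k} parameters")
        return self._predict(params, np.asarray(x, dtype=float), R)

    @property
    def numeric_id(self) -> int:
        return _MODEL_IDS[self.id]


MODELS: dict[str, ModelSpec] = {
    "predicted": ModelSpec(
        "predicted", 8, tuple(f"a{i}" for i in range(1, 9)), _predict_predicted
    ),
    "permuted": ModelSpec(
        "permuted", 8, tuple(f"b{i}" for i in range(1, 9)), _predict_permuted
    ),
    "unconstrained": ModelSpec(
        "unconstrained", 12, tuple(f"c{i}" for i in range(1, 13)),
        _predict_unconstrained,
    ),
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown model {model_id!r}") from None


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------


def _data_arrays(data: ParamPlotDataset):
    x = np.asarray(data.x, dtype=float)
    y = np.stack([data.series[p][0] for p in PARAM_NAMES])
    s = np.stack([data.series[p][1] for p in PARAM_NAMES])
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("chi-squared needs finite positive SEMs on every point")
    return x, y, s, float(data.reporter_level)


def condition_sems(data: ParamPlotDataset, rel_floor: float = 0.02) -> ParamPlotDataset:
    """Replace missing/zero SEMs so the dataset is usable for chi-squared.

    Anchor-normalized points carry SEM 0 and single-experiment datasets
    carry NaN; both are floored at ``rel_floor`` times the series scale
    (or the median finite SEM, whichever is larger).
    """
    series = {}
    for p, (m, s) in data.series.items():
        m = np.asarray(m, float)
        s = np.asarray(s, float).copy()
        finite = np.isfinite(s) & (s > 0)
        floor = max(
            rel_floor * np.nanmax(np.abs(m)),
            float(np.median(s[finite])) if finite.any() else 0.0,
        ) or 1.0
        s[~finite] = floor
        s = np.maximum(s, rel_floor * np.nanmax(np.abs(m)))
        series[p] = (m, s)
    return ParamPlotDataset(
        x=data.x, series=series, n=data.n, mode=data.mode,
        endogenous=data.endogenous, reporter_level=data.reporter_level,
    )


def chi_squared(
    model: ModelSpec, params: Sequence[float], data: ParamPlotDataset
) -> float:
    """Sum of squared standardized residuals over all four series."""
    x, y, s, R = _data_arrays(data)
    pred = model.predict(np.asarray(params, float), x, R)
    return float(np.sum(((y - pred) / s) ** 2))


@njit(cache=True)
def _chi2_kernel(mid, p, x, R, y, s):  # pragma: no cover - compiled
    n = x.size
    total = 0.0
    for i in range(n):
        xi = x[i]
        if mid == 0:
            m0 = p[4] * R * (p[0] + xi) / (p[1] + xi)
            m1 = p[5] * R * (p[2] + xi) / (p[3] + xi)
            m2 = p[6] * (p[1] + xi) / (p[3] + xi)
            m3 = p[7] * (p[0] + xi) / (p[2] + xi)
        elif mid == 1:
            m0 = p[4] * R * (p[0] + xi) / (p[3] + xi)
            m1 = p[5] * R * (p[1] + xi) / (p[2] + xi)
            m2 = p[6] * (p[2] + xi) / (p[1] + xi)
            m3 = p[7] * (p[3] + xi) / (p[0] + xi)
        else:
            m0 = p[8] * R * (p[0] + xi) / (p[4] + xi)
            m1 = p[9] * R * (p[1] + xi) / (p[5] + xi)
            m2 = p[10] * (p[2] + xi) / (p[6] + xi)
            m3 = p[11] * (p[3] + xi) / (p[7] + xi)
        total += ((y[0, i] - m0) / s[0, i]) ** 2
        total += ((y[1, i] - m1) / s[1, i]) ** 2
        total += ((y[2, i] - m2) / s[2, i]) ** 2
        total += ((y[3, i] - m3) / s[3, i]) ** 2
    return total


@njit(cache=True)
def _mh_kernel(mid, x, R, y, s, theta0, n_iter, burn, step0, seed, thin):
    # pragma: no cover - compiled
    np.random.seed(seed)
    k = theta0.size
    theta = theta0.copy()
    chi = _chi2_kernel(mid, np.exp(theta), x, R, y, s)
    n_keep = (n_iter - burn) // thin
    samples = np.empty((n_keep, k))
    chis = np.empty(n_keep)
    best_theta = theta.copy()
    best_chi = chi
    step = step0
    acc_total = 0
    acc_win = 0
    kept = 0
    for it in range(n_iter):
        prop = theta + step * np.random.standard_normal(k)
        inside = True
        for j in range(k):
            if prop[j] < LOG_LO or prop[j] > LOG_HI:
                inside = False
                break
        if inside:
            chi_p = _chi2_kernel(mid, np.exp(prop), x, R, y, s)
            if chi_p <= chi or np.random.random() < np.exp(-(chi_p - chi) / 2.0):
                theta = prop
                chi = chi_p
                acc_total += 1
                acc_win += 1
                if chi < best_chi:
                    best_chi = chi
                    best_theta = theta.copy()
        # adapt the proposal scale during burn-in only (frozen afterwards,
        # preserving detailed balance for the retained samples)
        if it < burn and (it + 1) % 200 == 0:
            rate = acc_win / 200.0
            if rate < 0.15:
                step *= 0.7
            elif rate > 0.4:
                step *= 1.4
            acc_win = 0
        if it >= burn and (it - burn) % thin == 0 and kept < n_keep:
            samples[kept] = theta
            chis[kept] = chi
            kept += 1
    return samples, chis, acc_total / n_iter, best_theta, best_chi, step


@dataclass
class MCMCChain:
    """Post-burn-in samples of one Metropolis-Hastings run (log-space walk,
    samples stored on the linear scale)."""

    model_id: str
    param_names: tuple[str, ...]
    samples: np.ndarray          # (n_kept, k), linear scale
    chi2_values: np.ndarray
    max_likelihood: np.ndarray   # linear-scale parameters at min chi^2
    chi2_min: float
    acceptance_rate: float
    seed: int
    iterations: int

    def posterior_mean_sd(self) -> tuple[np.ndarray, np.ndarray]:
        return self.samples.mean(axis=0), self.samples.std(axis=0, ddof=1)


def mh_sample(
    model: ModelSpec | Callable[[np.ndarray], float],
    data: ParamPlotDataset | None,
    iterations: int = 200_000,
    seed: int = 0,
    proposal_scale: float = 0.1,
    burn_frac: float = 0.3,
    thin: int = 10,
    theta0: np.ndarray | None = None,
    n_params: int | None = None,
) -> MCMCChain:
    """Random-walk Metropolis-Hastings over log-parameters.

    Flat priors on log-parameters over [1e-4, 1e4] (positivity by
    construction); the proposal scale adapts during burn-in only.
    Reproducible bit-for-bit given the seed.  A callable chi-squared target
    (with ``n_params``) may be passed instead of a model for generic use.
    """
    burn = int(burn_frac * iterations)
    if isinstance(model, ModelSpec):
        x, y, s, R = _data_arrays(data)
        k = model.k
        t0 = np.zeros(k) if theta0 is None else np.log(np.asarray(theta0, float))
        samples, chis, acc, best_t, best_chi, _ = _mh_kernel(
            model.numeric_id, x, R, y, s, t0,
            int(iterations), burn, proposal_scale, seed, int(thin),
        )
        model_id = model.id
        names = model.param_names
    else:
        if n_params is None:
            raise ValueError("n_params required for a callable target")
        k = n_params
        rng = np.random.default_rng(seed)
        t0 = np.zeros(k) if theta0 is None else np.log(np.asarray(theta0, float))
        chi_fn = model
        theta = t0.copy()
        chi = chi_fn(np.exp(theta))
        step = proposal_scale
        n_keep = (iterations - burn) // thin
        samples = np.empty((n_keep, k))
        chis = np.empty(n_keep)
        best_t, best_chi = theta.copy(), chi
        acc_n = 0
        win = 0
        kept = 0
        for it in range(iterations):
            prop = theta + step * rng.standard_normal(k)
            if np.all((prop >= LOG_LO) & (prop <= LOG_HI)):
                chi_p = chi_fn(np.exp(prop))
                if chi_p <= chi or rng.random() < np.exp(-(chi_p - chi) / 2.0):
                    theta, chi = prop, chi_p
                    acc_n += 1
                    win += 1
                    if chi < best_chi:
                        best_t, best_chi = theta.copy(), chi
            if it < burn and (it + 1) % 200 == 0:
                rate = win / 200.0
                step *= 0.7 if rate < 0.15 else (1.4 if rate > 0.4 else 1.0)
                win = 0
            if it >= burn and (it - burn) % thin == 0 and kept < n_keep:
                samples[kept] = theta
                chis[kept] = chi
                kept += 1
        acc = acc_n / iterations
        model_id = "custom"
        names = tuple(f"p{i+1}" for i in range(k))
    if acc <= 0.0:
        raise RuntimeError(
            "zero acceptance over the whole run: reduce proposal_scale"
        )
    return MCMCChain(
        model_id=model_id,
        param_names=names,
        samples=np.exp(samples),
        chi2_values=chis,
        max_likelihood=np.exp(best_t),
        chi2_min=float(best_chi),
        acceptance_rate=float(acc),
        seed=seed,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class FitReport:
    model_id: str
    k: int
    n: int
    chi2_min: float
    bic: float
    posterior_mean: dict[str, float]
    posterior_sd: dict[str, float]
    acceptance_rate: float
    halfmax_orderings: dict[str, float] = field(default_factory=dict)
    chain: MCMCChain | None = None


def _heuristic_start(model: ModelSpec, data: ParamPlotDataset) -> np.ndarray:
    """Data-driven initial point: LF roots near the median x, scales from
    the series means."""
    x, y, s, R = _data_arrays(data)
    xm = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
    means = y.mean(axis=1)
    scales = [means[0] / R, means[1] / R, means[2], means[3]]
    k_roots = model.k - 4
    start = np.empty(model.k)
    start[:k_roots] = xm
    start[k_roots:] = np.clip(scales, 1e-3, 1e3)
    return start


def _refine_chi2_min(model: ModelSpec, data: ParamPlotDataset, start: np.ndarray):
    x, y, s, R = _data_arrays(data)

    def f(logp):
        return _chi2_kernel(model.numeric_id, np.exp(logp), x, R, y, s)

    res = minimize(
        f, np.log(start), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
    )
    return float(res.fun), np.exp(res.x)


def model_compare(
    data: ParamPlotDataset,
    iterations: int = 200_000,
    seed: int = 0,
    keep_chains: bool = False,
) -> list[FitReport]:
    """Fit all three models and rank them by BIC = chi^2_min + k ln n.

    The unconstrained model runs a 1.5x longer chain to compensate for its
    extra parameters.  chi^2_min is the better of the chain optimum and a
    local refinement started from it.  ``n`` counts every data point across
    the four series.
    """
    n = 4 * len(data.x)
    reports = []
    predicted_best: np.ndarray | None = None
    for j, (mid, model) in enumerate(MODELS.items()):
        iters = int(iterations * (1.5 if mid == "unconstrained" else 1.0))
        start = _heuristic_start(model, data)
        chain = mh_sample(model, data, iterations=iters, seed=seed + j, theta0=start)
        chi_ref, p_ref = _refine_chi2_min(model, data, chain.max_likelihood)
        chi2_min = min(chain.chi2_min, chi_ref)
        chi_h, p_h = _refine_chi2_min(model, data, start)
        if chi_h < chi2_min:
            chi2_min, p_ref = chi_h, p_h
        if mid == "predicted":
            predicted_best = p_ref if chi_ref <= chain.chi2_min else chain.max_likelihood
        if mid == "unconstrained" and predicted_best is not None:
            # the predicted model is nested: its optimum embeds as
            # (c1..c12) = (a1,a3,a2,a1, a2,a4,a4,a3, a5,a6,a7,a8) and
            # guarantees the nesting inequality up to optimizer tolerance
            a = predicted_best
            embedded = np.array(
                [a[0], a[2], a[1], a[0], a[1], a[3], a[3], a[2],
                 a[4], a[5], a[6], a[7]]
            )
            chi_emb, _ = _refine_chi2_min(model, data, embedded)
            chi2_min = min(chi2_min, chi_emb)
        mean, sd = chain.posterior_mean_sd()
        report = FitReport(
            model_id=mid,
            k=model.k,
            n=n,
            chi2_min=chi2_min,
            bic=chi2_min + model.k * np.log(n),
            posterior_mean=dict(zip(model.param_names, mean)),
            posterior_sd=dict(zip(model.param_names, sd)),
            acceptance_rate=chain.acceptance_rate,
            chain=chain if keep_chains else None,
        )
        if mid == "predicted":
            report.halfmax_orderings = posterior_halfmax_ordering(
                chain, pairs=(("a1", "a3"), ("a2", "a4"))
            )
        reports.append(report)
    return sorted(reports, key=lambda r: r.bic)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def split_rhat(x: np.ndarray, n_splits: int = 4) -> float:
    """Split-R-hat of a 1-D chain over equal segments."""
    m = len(x) // n_splits
    if m < 2:
        return np.inf
    segs = np.stack([x[i * m : (i + 1) * m] for i in range(n_splits)])
    w = segs.var(axis=1, ddof=1).mean()
    b = m * segs.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (m - 1) / m * w + b / m
    return float(np.sqrt(var_plus / w))


def posterior_halfmax_ordering(
    chain: MCMCChain,
    pairs: Sequence[tuple[str, str]] = (("a1", "a3"), ("a2", "a4")),
    rhat_threshold: float = 1.1,
) -> dict[str, float]:
    """P(first > second) for parameter pairs, from posterior draws.

    For the predicted model, a2/a4 are the cofactor amounts at half-maximal
    A_max/A_min and a1/a3 those of their reciprocals.  Convergence is
    screened with split-R-hat; probabilities from unconverged chains are
    still returned but flagged via a warning key.
    """
    idx = {n: i for i, n in enumerate(chain.param_names)}
    out: dict[str, float] = {}
    warn = False
    for p, q in pairs:
        a = chain.samples[:, idx[p]]
        b = chain.samples[:, idx[q]]
        if max(split_rhat(np.log(a)), split_rhat(np.log(b))) > rhat_threshold:
            warn = True
        out[f"P({p}>{q})"] = float(np.mean(a > b))
    if warn:
        out["warning_unconverged"] = 1.0
    return out
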