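"""Ground-truth generators for competition assays, parameter plots and
Western calibrations.

Every generated dataset carries its ground truth, so downstream fitting,
classification and model-comparison stages can be tested end to end
without any external data.  Activities are computed from the symbolic
forward model (``derive_TU``) evaluated at each grid cell; replicate noise
is multiplicative log-normal (positive, roughly constant CV), with an
optional experiment-level scale jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp

from .config_formulas import Configuration, derive_TU
from .dose_response_fit import WesternCalibration, ParamPlotDataset

__all__ = [
    "GroundTruth",
    "AssayDesign",
    "NoiseModel",
    "default_truth",
    "generate_assay",
    "generate_param_plots",
    "generate_western",
    "activity_fn",
]


@dataclass
class GroundTruth:
    """A configuration plus concrete positive parameters.

    ``params`` maps scaffold symbol names (q1..q5, XT*, a3..a5, Y0, G, K,
    qp_*, alpha_*, beta_*, gamma_*) to values; the reporter symbol ``R``
    and the cofactor ``X`` are supplied per grid cell and must not appear.
    """

    configuration: Configuration
    params: dict[str, float]
    endogenous: float = 0.0
    scale: float = 100.0
    #: ng-equivalent dose -> model concentration conversion for the cofactor
    #: (transfection-efficiency bookkeeping; 1 = doses are concentrations)
    cofactor_scale: float = 1.0

    def to_json(self) -> str:
        d = {
            "configuration": self.configuration.id,
            "params": self.params,
            "endogenous": self.endogenous,
            "scale": self.scale,
            "cofactor_scale": self.cofactor_scale,
        }
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class AssayDesign:
    """Factorial design: reporter x cofactor grid, steroid doses, triplicates."""

    reporter_doses: tuple = (10.0, 35.0, 70.0, 140.0)
    cofactor_doses: tuple = (0.0, 10.0, 30.0, 100.0)
    steroid_doses: tuple = (0.0, 3.0, 30.0, 300.0)
    replicates: int = 3
    n_experiments: int = 1

    def __post_init__(self):
        if 0.0 not in self.steroid_doses:
            raise ValueError("design needs a zero (vehicle) steroid dose")
        if self.replicates < 1 or self.n_experiments < 1:
            raise ValueError("replicates and n_experiments must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal replicate noise + experiment scale jitter."""

    replicate_cv: float = 0.05
    experiment_cv: float = 0.10
    distribution: str = "lognormal"  # or 'gaussian' for sensitivity checks

    def __post_init__(self):
        if self.replicate_cv < 0 or self.experiment_cv < 0:
            raise ValueError("CVs must be >= 0")

    def _draw(self, cv: float, size, rng: np.random.Generator) -> np.ndarray:
        if cv == 0:
            return np.ones(size if size is not None else ())
        if self.distribution == "lognormal":
            s = np.sqrt(np.log1p(cv**2))
            return rng.lognormal(mean=-(s**2) / 2.0, sigma=s, size=size)
        return np.maximum(rng.normal(1.0, cv, size=size), 1e-12)

    def replicate_factors(self, size, rng) -> np.ndarray:
        return self._draw(self.replicate_cv, size, rng)

    def experiment_factor(self, rng) -> float:
        return float(self._draw(self.experiment_cv, None, rng))


# ---------------------------------------------------------------------------
# forward evaluation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _scaffold_table(config: Configuration):
    from .config_formulas import build_scaffold

    return build_scaffold(config)


@lru_cache(maxsize=None)
def _activity_lambdified(config: Configuration):
    tu = derive_TU(config)
    X, S = tu.x_symbol, tu.s_symbol
    params = tu.parameters
    A = (tu.T0 + tu.Tp * S) / (tu.U0 + tu.Up * S)
    fn = sp.lambdify([X, S] + params, A, modules="numpy")
    return [p.name for p in params], fn


def activity_fn(truth: GroundTruth):
    """Vectorized ``A(cofactor_total, steroid, reporter)`` for a truth.

    When the configuration places the cofactor at the CLS there is no
    separate reporter symbol (the cofactor *is* the CLS accelerator) and
    the reporter argument is inert.
    """
    names, fn = _activity_lambdified(truth.configuration)
    missing = [n for n in names if n != "R" and n not in truth.params]
    if missing:
        raise ValueError(f"ground truth missing parameters: {missing}")

    def A(x_total, steroid, reporter=1.0):
        vals = []
        for n in names:
            vals.append(reporter if n == "R" else truth.params[n])
        return truth.scale * fn(x_total, steroid, *vals)

    return A


def default_truth(
    config: Configuration,
    gr_decel_type: str | None = "LC",
    factor_decel_type: str | None = "LC",
) -> GroundTruth:
    """Reasonable CLS-valid parameters for any of the 18 configurations.

    Chosen so that the CLS regime holds across the default dose grids
    (limited accelerators stay below q*X ~ 1e-3), repression is a few-fold,
    and the repression midpoint sits inside the default steroid range.
    """
    cfg = config.with_types(factor_type=factor_decel_type, gr_type=gr_decel_type)
    tu = derive_TU(cfg)
    names = {p.name for p in tu.parameters}
    params: dict[str, float] = {}
    # Scales are chosen so the CLS occupancy term is order one at the
    # working inducer level (otherwise post-CLS loads cannot repress),
    # while the limited accelerators respect q*X_total <= ~1e-2 across the
    # default dose grids (doses up to ~140 ng-equivalents).
    base = {
        "q1": 1.0, "XT1": 1e7,          # first pre step: not limited
        "q2": 2e-8, "XT2": 5e4,         # pre-CLS slot: q*X = 1e-3, limited
        "q3": 7e-5,                     # CLS: q*R <= 1e-2 for R <= 140
        "q4": 0.02, "XT4": 50.0,        # post slots: order-one transfers
        "q5": 0.02, "XT5": 50.0,
        "a3": 1.0, "a4": 0.3, "a5": 0.3,
        "Y0": 10.0,
        "G": 300.0, "K": 30.0,
        "qp_gr": 0.01, "qp_f": 0.03,
        "alpha_gr": 1.0, "beta_gr": 0.3, "gamma_gr": 1.0,
        "alpha_f": 1.0, "beta_f": 0.3, "gamma_f": 1.0,
    }
    # activity weights depend on who feeds which post-CLS product: a
    # cofactor-fed product is productive, a receptor-fed product is a
    # low-productivity diversion (otherwise the receptor would induce)
    _, _, tab = _scaffold_table(cfg)
    if cfg.factor_mech.kind == "accelerator" and cfg.factor_pos == "after":
        base[f"a{tab['f_slot']}"] = 0.8
    if cfg.gr_mech.kind == "decelerator" and cfg.gr_pos == "after":
        # the decelerated branch must carry most of the activity, or load
        # relief at the CLS outweighs the productivity loss and the
        # receptor would induce instead of repress
        base["a4"] = 1.0
        base["a5"] = 1.0
    if cfg.gr_mech.kind == "accelerator":
        base[f"a{tab['gr_slot']}"] = 0.02
        for j in range(tab["gr_slot"] + 1, 6):
            base[f"a{j}"] = 0.01
    for n in names:
        if n in ("R",):
            continue
        if n not in base:
            raise KeyError(f"no default for scaffold parameter {n}")
        params[n] = base[n]
    # a pre-CLS accelerator cofactor must reach concentrations able to
    # occupy the CLS; ng-equivalent doses are converted up accordingly
    cof_scale = (
        300.0
        if (cfg.factor_mech.kind == "accelerator" and cfg.factor_pos == "before")
        else 1.0
    )
    return GroundTruth(configuration=cfg, params=params, cofactor_scale=cof_scale)


def tif2_like_truth(endogenous: float = 2.7) -> GroundTruth:
    """Coactivator-like ground truth: cofactor accelerates after the CLS,
    the receptor accelerates a low-productivity step after the cofactor.

    Parameters are tuned so the competition assay displays the canonical
    repression pattern (A_max up; A_min, IC50 down) with the default
    design, making the configuration uniquely recoverable end to end.
    """
    from .config_formulas import ACCELERATOR, Configuration

    cfg = Configuration(ACCELERATOR, "after", ACCELERATOR, "after", "GR-after-F")
    truth = default_truth(cfg)
    truth.params.update({"a4": 3.0, "q5": 0.08})
    truth.endogenous = endogenous
    return truth


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_assay(
    truth: GroundTruth,
    design: AssayDesign = AssayDesign(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    cofactor_id: str = "F",
) -> pd.DataFrame:
    """Simulate a full competition-assay table from a ground truth.

    Cell means come from the forward model at (reporter dose, cofactor
    total = endogenous + exogenous, steroid dose); replicates multiply in
    log-normal noise, experiments an additional scale jitter.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    A = activity_fn(truth)
    rows = []
    for exp in range(design.n_experiments):
        scale = noise.experiment_factor(rng)
        for rep_dose in design.reporter_doses:
            for cof_dose in design.cofactor_doses:
                x_total = (cof_dose + truth.endogenous) * truth.cofactor_scale
                for s_dose in design.steroid_doses:
                    mean = float(A(x_total, s_dose, reporter=rep_dose)) * scale
                    facs = noise.replicate_factors(design.replicates, rng)
                    for r in range(design.replicates):
                        rows.append(
                            {
                                "experiment": exp,
                                "reporter_dose": rep_dose,
                                "cofactor_id": cofactor_id,
                                "cofactor_dose": cof_dose,
                                "steroid_dose": s_dose,
                                "replicate": r,
                                "activity": mean * facs[r],
                            }
                        )
    df = pd.DataFrame(rows)
    sd = df.groupby(
        ["experiment", "reporter_dose", "cofactor_dose", "steroid_dose"]
    )["activity"].transform("std")
    df["activity_sd"] = sd.fillna(0.0)
    return df


def generate_param_plots(
    model_id: str,
    params: Mapping[str, float],
    x: Sequence[float],
    reporter: float = 1.0,
    n_experiments: int = 4,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> ParamPlotDataset:
    """Parameter-plot dataset drawn directly from a comparison-model structure.

    ``model_id`` is 'predicted', 'permuted' or 'unconstrained'; ``params``
    maps that model's parameter names (a1..a8 / b1..b8 / c1..c12) to
    positive values.  Four series with SEMs over ``n_experiments``
    simulated replicates.
    """
    from .bayes_compare import get_model  # local import to avoid a cycle

    model = get_model(model_id)
    x = np.asarray(x, dtype=float)
    theta = np.array([params[n] for n in model.param_names])
    truth = model.predict(theta, x, reporter)  # (4, n)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_experiments,) + truth.shape)
    for e in range(n_experiments):
        draws[e] = truth * noise.replicate_factors(truth.shape, rng)
    mean = draws.mean(axis=0)
    sem = draws.std(axis=0, ddof=1) / np.sqrt(n_experiments) if n_experiments > 1 \
        else np.full_like(truth, np.nan)
    if noise.replicate_cv == 0:
        # exact data: unit weights keep chi-squared finite
        sem = np.ones_like(truth)
        mean = truth.copy()
    from .dose_response_fit import PARAM_NAMES

    series = {p: (mean[i], sem[i]) for i, p in enumerate(PARAM_NAMES)}
    return ParamPlotDataset(
        x=x, series=series, n=np.full(len(x), n_experiments),
        mode="cofactor", reporter_level=reporter,
    )


def generate_western(
    cal: WesternCalibration,
    plasmid: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """OD table from a saturating expression curve with log-normal noise."""
    p = np.asarray(plasmid, dtype=float)
    rng = np.random.default_rng(seed)
    od = cal.m1 * p / (cal.m2 + p) * noise.replicate_factors(len(p), rng)
    return pd.DataFrame({"plasmid_ng": p, "od": od})
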