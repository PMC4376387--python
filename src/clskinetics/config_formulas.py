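"""Symbolic dose-response-parameter forms for receptor+cofactor configurations.

For a steroid receptor entering the chain as ``[GR] = G*S/(K+S)`` (as a
decelerator concentration anywhere, or an accelerator amount after the CLS)
and one other cofactor at amount ``X``, the activity is linear-fractional in
the steroid dose ``S``:

    A = T(S)/U(S) = (T(0) + T'*S) / (U(0) + U'*S)

with ``T`` and ``U`` linear in ``S`` and linear-fractional in ``X``.  The
four measurable dose-response parameters follow as

    A_max = T(0)/U(0),  A_min = T'/U',  IC50 = U(0)/U',
    A_max*IC50/A_min = T(0)/T'

and obey four coefficient compatibility conditions (shared numerators and
denominators) that arbitrary linear-fractional quartets would not.

Everything here is derived mechanically from the forward model in
:mod:`~clskinetics.kinetic_core` on a canonical 5-step scaffold
(two pre-CLS slots, the CLS carrying the reporter, two post-CLS slots);
nothing is transcribed from case tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import sympy as sp

from .kinetic_core import (
    DeceleratorSpec,
    LinearFractional,
    ReactionChain,
    ReactionStep,
    closed_form_dose_response,
)

__all__ = [
    "Mechanism",
    "Configuration",
    "SteroidReceptor",
    "TUForm",
    "DRParamForms",
    "ACCELERATOR",
    "DECELERATOR",
    "enumerate_configurations",
    "configuration_counts",
    "derive_TU",
    "dr_param_forms",
    "check_compatibility",
    "lf_shape",
    "LFShape",
    "numeric_form_functions",
]

POSITIONS = ("before", "at", "after")
DECEL_TYPES = ("LC", "LU", "LN", "PC", "PU", "PN")


@dataclass(frozen=True)
class Mechanism:
    """Accelerator, or one of six decelerator types (None = generic D)."""

    kind: str  # 'accelerator' | 'decelerator'
    decel_type: str | None = None

    def __post_init__(self):
        if self.kind not in ("accelerator", "decelerator"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if self.kind == "accelerator" and self.decel_type is not None:
            raise ValueError("decel_type only valid for decelerators")
        if self.decel_type is not None and self.decel_type not in DECEL_TYPES:
            raise ValueError(f"unknown decelerator type {self.decel_type!r}")

    @property
    def code(self) -> str:
        if self.kind == "accelerator":
            return "A"
        return self.decel_type or "D"


ACCELERATOR = Mechanism("accelerator")
DECELERATOR = Mechanism("decelerator")


@dataclass(frozen=True)
class Configuration:
    """A (mechanism, position) pair for the receptor and one cofactor.

    ``order`` disambiguates which factor acts at the earlier step; it is
    forced by the positions when they differ and equals ``'same-step'``
    when the two factors act at the same step (one accelerator, one
    decelerator).
    """

    factor_mech: Mechanism
    factor_pos: str
    gr_mech: Mechanism
    gr_pos: str
    order: str  # 'GR-before-F' | 'GR-after-F' | 'same-step'

    def __post_init__(self):
        if self.factor_pos not in POSITIONS or self.gr_pos not in POSITIONS:
            raise ValueError("positions must be before/at/after")
        if self.order not in ("GR-before-F", "GR-after-F", "same-step"):
            raise ValueError(f"bad order {self.order!r}")
        if self.order == "same-step":
            if self.factor_pos != self.gr_pos:
                raise ValueError("same-step requires equal positions")
            kinds = {self.factor_mech.kind, self.gr_mech.kind}
            if kinds != {"accelerator", "decelerator"}:
                raise ValueError(
                    "same-step requires exactly one accelerator and one decelerator"
                )
        else:
            pa, pb = POSITIONS.index(self.gr_pos), POSITIONS.index(self.factor_pos)
            if pa != pb:
                implied = "GR-before-F" if pa < pb else "GR-after-F"
                if self.order != implied:
                    raise ValueError("order inconsistent with distinct positions")
            if self.gr_pos == "at" and self.factor_pos == "at":
                raise ValueError("two factors cannot occupy distinct steps at the CLS")
        if self.gr_mech.kind == "accelerator" and self.gr_pos != "after":
            raise ValueError(
                "GR as an accelerator is only admissible after the CLS "
                "(it cannot repress otherwise)"
            )

    @property
    def id(self) -> str:
        return (
            f"F:{self.factor_mech.code}@{self.factor_pos}"
            f"|GR:{self.gr_mech.code}@{self.gr_pos}|{self.order}"
        )

    def with_types(
        self,
        factor_type: str | None = None,
        gr_type: str | None = None,
    ) -> "Configuration":
        """Copy with concrete decelerator subtypes filled in."""
        fm = self.factor_mech
        gm = self.gr_mech
        if factor_type is not None and fm.kind == "decelerator":
            fm = Mechanism("decelerator", factor_type)
        if gr_type is not None and gm.kind == "decelerator":
            gm = Mechanism("decelerator", gr_type)
        return Configuration(fm, self.factor_pos, gm, self.gr_pos, self.order)


@dataclass(frozen=True)
class SteroidReceptor:
    """Activated receptor concentration ``[GR] = G*S/(K+S)``."""

    G: float = 1.0
    K: float = 1.0

    def __post_init__(self):
        if isinstance(self.G, (int, float)) and self.G < 0:
            raise ValueError("G must be >= 0")
        if isinstance(self.K, (int, float)) and not self.K > 0:
            raise ValueError("K must be > 0")

    def conc(self, S):
        return self.G * S / (self.K + S)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _positional_arrangements() -> list[tuple[str, str, str]]:
    """Ordered (gr_pos, f_pos, order) tuples: 10 distinct-step + 3 same-step."""
    out = []
    # distinct-step, ordered
    unordered = [
        ("before", "before"),
        ("before", "at"),
        ("before", "after"),
        ("at", "after"),
        ("after", "after"),
    ]
    for pa, pb in unordered:
        out.append((pa, pb, "GR-before-F"))
        out.append((pb, pa, "GR-after-F") if pa != pb else (pa, pb, "GR-after-F"))
    # same-step
    for p in POSITIONS:
        out.append((p, p, "same-step"))
    return out


def enumerate_configurations() -> list[Configuration]:
    """All admissible configurations of the receptor and one cofactor.

    Counting convention: 10 ordered distinct-step positional arrangements
    plus 3 same-step arrangements; the receptor may act as a decelerator in
    all 13, or as an accelerator in the 5 arrangements that place it after
    the CLS — 18 configurations in total.  The cofactor defaults to an
    accelerator except where the same-step constraint forces a decelerator.
    """
    configs: list[Configuration] = []
    for gr_pos, f_pos, order in _positional_arrangements():
        if order == "same-step":
            # GR as decelerator, factor as accelerator — always admissible
            configs.append(
                Configuration(ACCELERATOR, f_pos, DECELERATOR, gr_pos, order)
            )
            if gr_pos == "after":
                # GR as accelerator forces the factor to be the decelerator
                configs.append(
                    Configuration(DECELERATOR, f_pos, ACCELERATOR, gr_pos, order)
                )
        else:
            configs.append(
                Configuration(ACCELERATOR, f_pos, DECELERATOR, gr_pos, order)
            )
            if gr_pos == "after":
                configs.append(
                    Configuration(ACCELERATOR, f_pos, ACCELERATOR, gr_pos, order)
                )
    return configs


def configuration_counts() -> dict[str, int]:
    configs = enumerate_configurations()
    gr_d = sum(1 for c in configs if c.gr_mech.kind == "decelerator")
    gr_a = sum(1 for c in configs if c.gr_mech.kind == "accelerator")
    return {
        "total": len(configs),
        "gr_decelerator": gr_d,
        "gr_accelerator_after_cls": gr_a,
        "ordered_positional": len(
            {(c.gr_pos, c.factor_pos, c.order) for c in configs if c.order != "same-step"}
        ),
        "same_step": len(
            {(c.gr_pos, c.factor_pos) for c in configs if c.order == "same-step"}
        ),
        # the headline count does not expand the six decelerator subtypes;
        # reported separately for reference
        "gr_decelerator_subtype_expanded": gr_d * len(DECEL_TYPES),
    }


# ---------------------------------------------------------------------------
# symbolic derivation on the canonical scaffold
# ---------------------------------------------------------------------------

# scaffold slots: 1, 2 pre-CLS; 3 CLS (reporter); 4, 5 post-CLS
_SLOT_OF = {
    ("before", "single"): 2,
    ("before", "first"): 1,
    ("before", "second"): 2,
    ("at", "single"): 3,
    ("after", "single"): 4,
    ("after", "first"): 4,
    ("after", "second"): 5,
}


def _decel_params(prefix: str, decel_type: str | None):
    """(alpha, beta, gamma, q') sympy parameters for a decelerator subtype."""
    qp = sp.Symbol(f"qp_{prefix}", positive=True)
    alpha = sp.Symbol(f"alpha_{prefix}", nonnegative=True)
    beta = sp.Symbol(f"beta_{prefix}", nonnegative=True)
    gamma = sp.Symbol(f"gamma_{prefix}", nonnegative=True)
    if decel_type is None:
        return alpha, beta, gamma, qp
    mode, bind = decel_type[0], decel_type[1]
    if bind == "C":
        alpha = sp.Integer(0)
    elif bind == "U":
        gamma = sp.Integer(0)
    elif bind == "N":
        gamma = alpha
    if mode == "L":
        beta = sp.Integer(0)
    return alpha, beta, gamma, qp


@dataclass
class TUForm:
    """``A = (T0 + Tp*S)/(U0 + Up*S)`` with coefficients in the cofactor X.

    ``T0, Tp, U0, Up`` are sympy expressions linear in ``x_symbol``; all
    remaining free symbols are positive composite constants of the hidden
    reactions (plus receptor scale ``G`` and steroid affinity ``K``).
    """

    config: Configuration
    x_symbol: sp.Symbol
    s_symbol: sp.Symbol
    T0: sp.Expr
    Tp: sp.Expr
    U0: sp.Expr
    Up: sp.Expr
    gr_symbols: dict[str, sp.Symbol] = field(default_factory=dict)

    @property
    def parameters(self) -> list[sp.Symbol]:
        syms = set()
        for e in (self.T0, self.Tp, self.U0, self.Up):
            syms |= sp.sympify(e).free_symbols
        syms.discard(self.x_symbol)
        return sorted(syms, key=lambda s: s.name)

    def linear_coeffs(self, expr) -> tuple[sp.Expr, sp.Expr]:
        p = sp.Poly(sp.expand(expr), self.x_symbol)
        if p.degree() > 1:
            raise ValueError("expression not linear in the cofactor")
        return p.coeff_monomial(1), p.coeff_monomial(self.x_symbol)


def build_scaffold(
    config: Configuration,
    x_symbol: sp.Symbol | None = None,
    s_symbol: sp.Symbol | None = None,
) -> tuple[ReactionChain, list[DeceleratorSpec], dict]:
    """Symbolic 5-step chain + decelerators realizing a configuration.

    The varied cofactor amount enters as accelerator total or free
    decelerator concentration ``X``; the receptor enters as
    ``G*S/(K+S)``.  Returns the chain, the decelerator list and a symbol
    table (X, S, G, K, R, Y0, ...).
    """
    X = x_symbol or sp.Symbol("X", nonnegative=True)
    S = s_symbol or sp.Symbol("S", nonnegative=True)
    G = sp.Symbol("G", nonnegative=True)
    K = sp.Symbol("K", positive=True)
    R = sp.Symbol("R", positive=True)
    Y0 = sp.Symbol("Y0", positive=True)
    gr_conc = G * S / (K + S)

    qs = [sp.Symbol(f"q{i}", positive=True) for i in range(1, 6)]
    xts: list = [sp.Symbol(f"XT{i}", positive=True) for i in range(1, 6)]
    xts[2] = R  # the reporter is the CLS accelerator

    decels: list[DeceleratorSpec] = []

    def place(actor: str, mech: Mechanism, pos: str, slot_role: str, amount):
        slot = 3 if pos == "at" else _SLOT_OF[(pos, slot_role)]
        if mech.kind == "accelerator":
            xts[slot - 1] = amount
        else:
            alpha, beta, gamma, qp = _decel_params(actor, mech.decel_type)
            decels.append(
                DeceleratorSpec(
                    step=slot, conc=amount, q_prime=qp,
                    alpha=alpha, beta=beta, gamma=gamma,
                )
            )
        return slot

    if config.order == "same-step":
        f_role = gr_role = "single"
    else:
        if config.gr_pos == config.factor_pos:
            gr_role, f_role = (
                ("first", "second")
                if config.order == "GR-before-F"
                else ("second", "first")
            )
        else:
            gr_role = f_role = "single"

    f_slot = place("f", config.factor_mech, config.factor_pos, f_role, X)
    gr_slot = place("gr", config.gr_mech, config.gr_pos, gr_role, gr_conc)

    steps = [ReactionStep(i + 1, qs[i], xts[i]) for i in range(5)]
    weights = {i: sp.Symbol(f"a{i}", positive=True) for i in (3, 4, 5)}
    chain = ReactionChain(steps, cls_index=3, activity_weights=weights)
    table = {
        "X": X, "S": S, "G": G, "K": K, "R": R, "Y0": Y0,
        "f_slot": f_slot, "gr_slot": gr_slot,
        "q": qs, "XT": xts, "weights": weights,
    }
    return chain, decels, table


@lru_cache(maxsize=None)
def _derive_TU_cached(config: Configuration) -> TUForm:
    chain, decels, tab = build_scaffold(config)
    X, S, Y0, K = tab["X"], tab["S"], tab["Y0"], tab["K"]
    lf = closed_form_dose_response(chain, decels)
    A = lf.b * Y0 / (1 + lf.d * Y0)
    T, U = sp.fraction(sp.cancel(sp.together(A)))
    for e, name in ((T, "T"), (U, "U")):
        if sp.degree(sp.Poly(sp.expand(e), S), S) > 1:
            raise RuntimeError(f"{name} not linear in S for {config.id}")
        if sp.degree(sp.Poly(sp.expand(e), X), X) > 1:
            raise RuntimeError(f"{name} not linear in X for {config.id}")
    # fix overall sign so that U's constant coefficient is positive
    u00 = sp.expand(U).subs({S: 0, X: 0})
    probe = {s: sp.Rational(1, 2) for s in u00.free_symbols}
    if u00.subs(probe) < 0:
        T, U = -T, -U
    T = sp.expand(T)
    U = sp.expand(U)
    return TUForm(
        config=config,
        x_symbol=X,
        s_symbol=S,
        T0=sp.expand(T.subs(S, 0)),
        Tp=sp.expand(sp.diff(T, S)),
        U0=sp.expand(U.subs(S, 0)),
        Up=sp.expand(sp.diff(U, S)),
        gr_symbols={"G": tab["G"], "K": K},
    )


def derive_TU(
    config: Configuration, gr: SteroidReceptor | None = None
) -> TUForm:
    """Symbolic T(S), U(S) for a configuration.

    The chain is built in :mod:`kinetic_core` with a generic cofactor at
    its position, ``[GR] = G*S/(K+S)`` substituted as decelerator
    concentration or accelerator amount, and the fractions cleared.  The
    result is linear in S and linear-fractional in the cofactor.  When a
    concrete :class:`SteroidReceptor` is supplied its G, K values are
    substituted into the returned form.
    """
    tu = _derive_TU_cached(config)
    if gr is None:
        return tu
    sub = {tu.gr_symbols["G"]: gr.G, tu.gr_symbols["K"]: gr.K}
    return TUForm(
        config=tu.config,
        x_symbol=tu.x_symbol,
        s_symbol=tu.s_symbol,
        T0=tu.T0.subs(sub),
        Tp=tu.Tp.subs(sub),
        U0=tu.U0.subs(sub),
        Up=tu.Up.subs(sub),
        gr_symbols=tu.gr_symbols,
    )


# ---------------------------------------------------------------------------
# dose-response parameter forms
# ---------------------------------------------------------------------------


@dataclass
class DRParamForms:
    """A_max, A_min, IC50 and A_max*IC50/A_min as LFs in the cofactor."""

    amax: LinearFractional
    amin: LinearFractional
    ic50: LinearFractional | None
    ratio: LinearFractional | None
    ic50_defined: bool = True
    ec50: object | None = None  # induction analogue (1/W at S=0), when asked

    def all_four(self):
        if not self.ic50_defined:
            raise ValueError("IC50/ratio undefined (no repression: U' = 0)")
        return (self.amax, self.amin, self.ic50, self.ratio)


def dr_param_forms(tu: TUForm) -> DRParamForms:
    """The four parameter plots vs cofactor from one TU form.

    ``A_max = T(0)/U(0)``, ``A_min = T'/U'``, ``IC50 = U(0)/U'``,
    ``ratio = T(0)/T'``.  When ``U' = 0`` (no steroid dependence at all)
    IC50 and the ratio are flagged undefined.
    """
    t00, t01 = tu.linear_coeffs(tu.T0)
    tp0, tp1 = tu.linear_coeffs(tu.Tp)
    u00, u01 = tu.linear_coeffs(tu.U0)
    up0, up1 = tu.linear_coeffs(tu.Up)
    amax = LinearFractional(t00, t01, u00, u01)
    undefined = (up0 == 0 and up1 == 0) or (
        isinstance(up0, (int, float)) and isinstance(up1, (int, float))
        and up0 == 0 and up1 == 0
    )
    if undefined:
        return DRParamForms(
            amax=amax,
            amin=amax,
            ic50=None,
            ratio=None,
            ic50_defined=False,
        )
    return DRParamForms(
        amax=amax,
        amin=LinearFractional(tp0, tp1, up0, up1),
        ic50=LinearFractional(u00, u01, up0, up1),
        ratio=LinearFractional(t00, t01, tp0, tp1),
    )


def check_compatibility(
    forms: DRParamForms, tol: float = 1e-9
) -> dict[str, bool]:
    """The four coefficient-proportionality conditions.

    a) num(A_max) == num(ratio);  b) num(A_min) == den(ratio);
    c) den(A_max) == num(IC50);   d) den(A_min) == den(IC50)
    — each as proportionality of normalized (constant, slope) pairs.
    Works on numeric or symbolic coefficients.
    """
    amax, amin, ic50, ratio = forms.all_four()

    def pair_num(lf):
        return lf.a, lf.b

    def pair_den(lf):
        return lf.c, lf.d

    def proportional(p, q) -> bool:
        cross = p[0] * q[1] - p[1] * q[0]
        if isinstance(cross, sp.Expr):
            return sp.simplify(cross) == 0
        scale = abs(p[0] * q[1]) + abs(p[1] * q[0])
        return abs(cross) <= tol * max(scale, 1e-300)

    return {
        "a": proportional(pair_num(amax), pair_num(ratio)),
        "b": proportional(pair_num(amin), pair_den(ratio)),
        "c": proportional(pair_den(amax), pair_num(ic50)),
        "d": proportional(pair_den(amin), pair_den(ic50)),
    }


# ---------------------------------------------------------------------------
# qualitative shape of a linear-fractional plot
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LFShape:
    direction: str  # 'inc' | 'dec' | 'const'
    half_max: float
    reciprocal_half_max: float
    linear_through_origin: bool
    positive_intercept: bool


def lf_shape(
    lf: LinearFractional,
    x_range: tuple[float, float] | None = None,
    const_tol: float = 0.05,
) -> LFShape:
    """Algebraic classification of ``y = (a+bx)/(c+dx)``.

    y increases iff ``ad < bc``, decreases iff ``bc < ad``; constant within
    a tolerance band ``|ad - bc| <= const_tol * |ad + bc|``.  The x for
    half-maximal y is ``c/d`` and for half-maximal 1/y is ``a/b``.
    """
    a, b, c, d = (float(v) for v in lf.coefficients())
    if c == 0 and d == 0:
        raise ValueError("degenerate linear-fractional function")
    det = b * c - a * d
    scale = abs(a * d + b * c)
    if abs(det) <= const_tol * scale or det == 0:
        direction = "const"
    else:
        direction = "inc" if det > 0 else "dec"
    half_max = c / d if d != 0 else np.inf
    recip_half_max = a / b if b != 0 else np.inf
    # y = b x / c exactly when a = d = 0 (tolerance relative to the range)
    if x_range is not None:
        xm = max(abs(x_range[0]), abs(x_range[1]), 1e-300)
        lto = abs(a) <= const_tol * abs(b) * xm and abs(d) * xm <= const_tol * abs(c)
    else:
        lto = a == 0 and d == 0
    positive_intercept = c != 0 and (a / c) > 0
    return LFShape(
        direction=direction,
        half_max=half_max,
        reciprocal_half_max=recip_half_max,
        linear_through_origin=bool(lto),
        positive_intercept=bool(positive_intercept),
    )


# ---------------------------------------------------------------------------
# fast numeric evaluation for feasibility scans
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def numeric_form_functions(config: Configuration):
    """Vectorized coefficient evaluators for one configuration.

    Returns ``(param_names, fn)`` where ``fn(values)`` maps an array of
    shape (n_params, m) of positive parameter draws to a dict of
    coefficient arrays ``{'t00': ..., ..., 'up1': ...}`` — the linear-in-X
    coefficients of T(0), T', U(0), U'.
    """
    tu = derive_TU(config)
    params = tu.parameters
    names = [p.name for p in params]
    coeff_exprs = {}
    for tag, expr in (("t0", tu.T0), ("tp", tu.Tp), ("u0", tu.U0), ("up", tu.Up)):
        c0, c1 = tu.linear_coeffs(expr)
        coeff_exprs[tag + "0"] = c0
        coeff_exprs[tag + "1"] = c1
    funcs = {
        k: sp.lambdify(params, v, modules="numpy") for k, v in coeff_exprs.items()
    }

    def fn(values: np.ndarray) -> dict[str, np.ndarray]:
        cols = [np.asarray(values[i]) for i in range(len(params))]
        m = np.broadcast_shapes(*(c.shape for c in cols)) if cols else ()
        out = {}
        for k, f in funcs.items():
            v = f(*cols)
            out[k] = np.broadcast_to(np.asarray(v, dtype=float), m).copy()
        return out

    return names, fn
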