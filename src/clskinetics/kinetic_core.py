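"""Equilibrium forward model of a gene-expression reaction chain.

A chain is an ordered sequence of complex-building reactions
``Y_{i-1} + X_i <-> Y_i`` with affinity constants ``q_i``.  One step is the
concentration-limited step (CLS): its accelerator is limited with respect to
its binding affinity while every accelerator downstream of it is in excess.
Under that regime the activity (a weighted sum of the products at and after
the CLS) is an exact linear-fractional function of the inducer concentration
``[Y_0]``, built here by composing per-step linear-fractional maps.  A
brute-force numeric equilibrium solver with *unapproximated* mass
conservation is provided as an independent oracle.

Decelerators (enzymatic-inhibitor-like factors) attach to individual steps.
A decelerator binds the accelerator with strength ``gamma*q'`` and/or the
product with strength ``alpha*q'``; the bound product retains a fraction
``beta`` of its productivity.  The six classical inhibition types are the
corners of this parameterization (competitive alpha=0, uncompetitive
gamma=0, noncompetitive alpha=gamma, linear beta=0, partial beta>0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, root

__all__ = [
    "ReactionStep",
    "ReactionChain",
    "DeceleratorSpec",
    "LinearFractional",
    "OligomerSpec",
    "CLSReport",
    "solve_equilibrium_numeric",
    "activity_from_solution",
    "closed_form_dose_response",
    "check_cls_conditions",
    "hill_fit",
    "hit_and_run_steady_state",
    "oligomer_effective_step",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionStep:
    """One complex-building reaction ``Y_{i-1} + X_i <-> Y_i``.

    Parameters
    ----------
    index
        1-based position of the step in the chain.
    q
        Equilibrium/affinity constant (1/concentration).  Must be > 0 for
        numeric chains; symbolic entries are accepted as-is.
    X_total
        Total accelerator concentration (arbitrary but consistent units).
    """

    index: int
    q: object
    X_total: object

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("step index is 1-based")
        if _is_number(self.q) and not self.q > 0:
            raise ValueError(f"step {self.index}: q must be > 0")
        if _is_number(self.X_total) and self.X_total < 0:
            raise ValueError(f"step {self.index}: X_total must be >= 0")


@dataclass(frozen=True)
class DeceleratorSpec:
    """A decelerator acting on one reaction step.

    ``conc`` is the *free* decelerator concentration, treated as a fixed
    external parameter (decelerator in excess; no conservation equation).
    """

    step: int
    conc: object
    q_prime: object
    alpha: object = 0.0
    beta: object = 0.0
    gamma: object = 1.0

    def __post_init__(self) -> None:
        for name in ("conc", "q_prime", "alpha", "beta", "gamma"):
            v = getattr(self, name)
            if _is_number(v) and v < 0:
                raise ValueError(f"decelerator {name} must be >= 0")
        if _is_number(self.q_prime) and not self.q_prime > 0:
            raise ValueError("q_prime must be > 0")

    @property
    def mechanism(self) -> str:
        """Two-letter label, e.g. ``'LC'`` = linear competitive.

        Only defined for numeric specs; binding-mode letter is C/U/N and
        productivity letter is L (beta=0) or P (beta>0).
        """
        if not all(_is_number(getattr(self, k)) for k in ("alpha", "beta", "gamma")):
            raise ValueError("mechanism label undefined for symbolic parameters")
        if self.alpha == 0:
            mode = "C"
        elif self.gamma == 0:
            mode = "U"
        elif self.alpha == self.gamma:
            mode = "N"
        else:
            mode = "M"  # mixed; not one of the six canonical types
        return ("L" if self.beta == 0 else "P") + mode


@dataclass
class ReactionChain:
    """Ordered reaction steps plus CLS location and activity weights.

    ``activity_weights`` maps step index -> weight ``a_i`` of product
    ``Y_i`` in the total activity.  Weights may only sit on products at or
    after the (last) CLS; by default every such product gets weight 1
    (``include_cls_product`` controls whether the CLS product itself
    contributes).
    """

    steps: list[ReactionStep]
    cls_index: int | Sequence[int]
    inducer_conc: float = 1.0
    activity_weights: dict[int, object] | None = None
    include_cls_product: bool = True

    def __post_init__(self) -> None:
        idx = [s.index for s in self.steps]
        if idx != list(range(1, len(self.steps) + 1)):
            raise ValueError("steps must be contiguous and 1-based")
        for c in self.cls_indices:
            if c not in idx:
                raise ValueError(f"cls_index {c} not a step of the chain")

    @property
    def cls_indices(self) -> list[int]:
        if isinstance(self.cls_index, int):
            return [self.cls_index]
        return sorted(self.cls_index)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def weights(self) -> dict[int, object]:
        """Resolved activity weights (defaults applied and validated)."""
        last_cls = self.cls_indices[-1]
        first = last_cls if self.include_cls_product else last_cls + 1
        if self.activity_weights is None:
            w = {i: 1.0 for i in range(first, self.n_steps + 1)}
        else:
            w = dict(self.activity_weights)
            for i in w:
                if i < first:
                    raise ValueError(
                        f"activity weight on step {i} precedes the admissible "
                        f"range (>= {first})"
                    )
        if not w or all(_is_number(v) and v == 0 for v in w.values()):
            raise ValueError("at least one activity weight must be nonzero")
        return w

    # -- JSON config round trip --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "steps": [asdict(s) for s in self.steps],
            "cls_index": self.cls_index,
            "inducer_conc": self.inducer_conc,
            "activity_weights": (
                None
                if self.activity_weights is None
                else {str(k): v for k, v in self.activity_weights.items()}
            ),
            "include_cls_product": self.include_cls_product,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactionChain":
        w = d.get("activity_weights")
        return cls(
            steps=[ReactionStep(**s) for s in d["steps"]],
            cls_index=d["cls_index"],
            inducer_conc=d.get("inducer_conc", 1.0),
            activity_weights=None if w is None else {int(k): v for k, v in w.items()},
            include_cls_product=d.get("include_cls_product", True),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ReactionChain":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class OligomerSpec:
    """Accelerator that first oligomerizes with a superabundant partner Z."""

    r: float
    Z_total: float

    def __post_init__(self) -> None:
        if _is_number(self.r) and not self.r > 0:
            raise ValueError("r must be > 0")
        if _is_number(self.Z_total) and self.Z_total < 0:
            raise ValueError("Z_total must be >= 0")


class LinearFractional:
    """``y = (a + b*x) / (c + d*x)`` — closed under composition.

    Coefficients may be floats or sympy expressions.  ``canonical()``
    normalizes ``c`` to 1 when ``c != 0`` (else ``d`` to 1).
    """

    __slots__ = ("a", "b", "c", "d")

    def __init__(self, a, b, c, d):
        if _is_number(c) and _is_number(d) and c == 0 and d == 0:
            raise ValueError("c and d cannot both be zero")
        self.a, self.b, self.c, self.d = a, b, c, d

    def __call__(self, x):
        return (self.a + self.b * x) / (self.c + self.d * x)

    def compose(self, inner: "LinearFractional") -> "LinearFractional":
        """Return self(inner(x)) as a LinearFractional."""
        a1, b1, c1, d1 = self.a, self.b, self.c, self.d
        a2, b2, c2, d2 = inner.a, inner.b, inner.c, inner.d
        return LinearFractional(
            a1 * c2 + b1 * a2,
            a1 * d2 + b1 * b2,
            c1 * c2 + d1 * a2,
            c1 * d2 + d1 * b2,
        )

    def canonical(self) -> "LinearFractional":
        if _is_number(self.c) and self.c == 0:
            s = self.d
        else:
            s = self.c
        return LinearFractional(self.a / s, self.b / s, self.c / s, self.d / s)

    def coefficients(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LinearFractional(a={self.a}, b={self.b}, c={self.c}, d={self.d})"


def _is_number(v) -> bool:
    return isinstance(v, (int, float, np.integer, np.floating))


# ---------------------------------------------------------------------------
# per-step decelerator algebra
# ---------------------------------------------------------------------------


def _decel_factors(decels_at_step):
    """Combined (offset, prod_bind, transfer_mult, mass_mult) for one step.

    offset        gamma*q'*[D]      (accelerator sequestration)
    prod_bind     alpha*q'*[D]      (product sequestration)
    transfer_mult 1 + alpha*beta*q'*[D]  (effective product passed on)
    mass_mult     1 + alpha*q'*[D]      (total product mass formed)

    Multiple decelerators on the same step combine multiplicatively on the
    binding equilibria (independent binding).
    """
    off = 0.0
    pb = 0.0
    tm = 1.0
    mm = 1.0
    for d in decels_at_step:
        e = d.q_prime * d.conc
        off = off + d.gamma * e
        pb = pb + d.alpha * e
        tm = tm * (1 + d.alpha * d.beta * e)
        mm = mm * (1 + d.alpha * e)
    return off, pb, tm, mm


def _group_decels(chain: ReactionChain, decels: Sequence[DeceleratorSpec] | None):
    by_step: dict[int, list[DeceleratorSpec]] = {}
    for d in decels or []:
        if d.step < 1 or d.step > chain.n_steps:
            raise ValueError(f"decelerator attached to undefined step {d.step}")
        by_step.setdefault(d.step, []).append(d)
    return by_step


def _step_roles(chain: ReactionChain, threshold: float = 0.01) -> list[str]:
    """Label each step 'pre', 'cls' or 'post'.

    With a single CLS the labels follow position alone.  With multiple CLS
    steps, a step between two CLSs is post-CLS of the earlier one when its
    accelerator is not limited (q*X_total >= threshold), otherwise it opens
    the pre-CLS block of the next.
    """
    cls_set = set(chain.cls_indices)
    roles = []
    for s in chain.steps:
        if s.index in cls_set:
            roles.append("cls")
        elif s.index < chain.cls_indices[0]:
            roles.append("pre")
        elif s.index > chain.cls_indices[-1]:
            roles.append("post")
        else:
            qx = s.q * s.X_total
            limited = _is_number(qx) and qx < threshold
            roles.append("pre" if limited else "post")
    return roles


# ---------------------------------------------------------------------------
# closed-form dose-response
# ---------------------------------------------------------------------------


def closed_form_dose_response(
    chain: ReactionChain,
    decels: Sequence[DeceleratorSpec] | None = None,
) -> LinearFractional:
    """Activity vs inducer ``[Y_0]`` as ``A = V*y0 / (1 + W*y0)``.

    Built by composing the per-step linear-fractional maps of the CLS
    regime: saturating pre-CLS steps, a CLS step carrying the downstream
    pseudo-first-order load, and proportional post-CLS steps.  Decelerators
    modify the relevant numerators and denominators.  ``A_max = V/W`` and
    ``EC50 = 1/W`` are recoverable from the returned coefficients.
    """
    by_step = _group_decels(chain, decels)
    roles = _step_roles(chain)
    weights = chain.weights()
    last_cls = chain.cls_indices[-1]

    n = chain.n_steps
    # transfer / mass factors for every step (used for loads and weights)
    transfer = {}
    mass = {}
    for s in chain.steps:
        off, _pb, tm, mm = _decel_factors(by_step.get(s.index, ()))
        transfer[s.index] = s.q * s.X_total * tm / (1 + off)
        mass[s.index] = s.q * s.X_total * mm / (1 + off)

    def load_after(c: int) -> object:
        """Pseudo-first-order load of the post block following CLS c."""
        j = c + 1
        block = []
        while j <= n and roles[j - 1] == "post":
            block.append(j)
            j += 1
        L = 0.0
        for j in reversed(block):
            L = mass[j] + transfer[j] * L
        return L

    # fold the chain into y = N*y0 / (D + S*y0)
    N, D, S = 1.0, 1.0, 0.0
    for s, role in zip(chain.steps, roles):
        off, _pb, tm, mm = _decel_factors(by_step.get(s.index, ()))
        if role == "pre":
            ni, di, si = s.q * s.X_total * tm, 1 + off, s.q * mm
        elif role == "cls":
            L = load_after(s.index)
            ni = s.q * s.X_total * tm
            di = 1 + off
            si = s.q * (mm + tm * L)
        else:  # post
            ni, di, si = transfer[s.index], 1.0, 0.0
        # compose: y -> ni*y/(di + si*y) applied to N*y0/(D + S*y0)
        N, D, S = ni * N, di * D, di * S + si * N
        if s.index == last_cls:
            N_cls, D_cls, S_cls = N, D, S

    # weighted sum of products at/after the last CLS: all proportional to
    # the CLS product, multiplier M = a_c + t_{c+1}(a_{c+1} + ...)
    M = weights.get(n, 0.0)
    for j in range(n - 1, last_cls - 1, -1):
        M = weights.get(j, 0.0) + transfer[j + 1] * M

    V = M * N_cls / D_cls
    W = S_cls / D_cls
    return LinearFractional(0.0, V, 1.0, W)


# ---------------------------------------------------------------------------
# CLS regime diagnostics
# ---------------------------------------------------------------------------


@dataclass
class CLSReport:
    """Advisory report from :func:`check_cls_conditions`."""

    roles: dict[int, str]
    limited_margin: dict[int, float]  # q_i * X_i^T for steps required limited
    excess_margin: dict[int, float]   # X_j^T / (estimated bound) for post steps
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def check_cls_conditions(chain: ReactionChain, threshold: float = 0.01) -> CLSReport:
    """Classify steps as pre-CLS / CLS / post-CLS and check regime validity.

    The bilinear mass-conservation structure requires accelerators to be
    limited with respect to their affinities (``q_i * X_i^T << 1``) at every
    step from the one following the first pre-CLS step through the CLS, and
    post-CLS accelerators to be in excess of their bound concentrations.
    """
    roles = _step_roles(chain, threshold)
    role_map = {s.index: r for s, r in zip(chain.steps, roles)}

    limited_margin: dict[int, float] = {}
    violations: list[str] = []
    for s, role in zip(chain.steps, roles):
        # mass conservation of a pre-CLS step i-1 is bilinear only when the
        # products downstream of it stay small, which needs the accelerator
        # of step i limited: q_i * X_i^T << 1.  The first step of each
        # pre-block carries no such requirement.
        prev_role = role_map.get(s.index - 1)
        if role in ("pre", "cls") and prev_role == "pre":
            qx = float(s.q * s.X_total)
            limited_margin[s.index] = qx
            if qx >= threshold:
                violations.append(
                    f"step {s.index} ({role}): q*X_total = {qx:.3g} >= {threshold:g}"
                )

    # post-CLS excess: bound product at step j is at most the CLS accelerator
    # total propagated through the post-block transfers.
    excess_margin: dict[int, float] = {}
    for c in chain.cls_indices:
        y_bound = float(chain.steps[c - 1].X_total)
        j = c + 1
        while j <= chain.n_steps and role_map[j] == "post":
            s = chain.steps[j - 1]
            y_bound = float(s.q * s.X_total) * y_bound
            xt = float(s.X_total)
            margin = np.inf if y_bound == 0 else xt / y_bound
            excess_margin[j] = margin
            if margin < 1.0 / threshold / 10:
                # advisory only: bound estimate is an upper bound
                pass
            j += 1

    return CLSReport(
        roles=role_map,
        limited_margin=limited_margin,
        excess_margin=excess_margin,
        violations=violations,
    )


# ---------------------------------------------------------------------------
# brute-force numeric equilibrium (the oracle)
# ---------------------------------------------------------------------------


def solve_equilibrium_numeric(
    chain: ReactionChain,
    decels: Sequence[DeceleratorSpec] | None = None,
    y0: float | None = None,
    rtol: float = 1e-10,
    n_starts: int = 3,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Solve the exact equilibrium — no CLS approximation.

    Equilibrium relations ``[Y_i] = q_i [X_i] [Y_{i-1}]`` together with the
    exact mass-conservation sums ``[X_i] + sum_{j>=i} [Y_j] = X_i^T``
    (decelerator-bound species included) are solved for the free accelerator
    concentrations on a log scale with multistart.  Returns
    ``{step: ([X_i], [Y_i])}`` with ``[Y_i]`` the effective product
    (free plus beta-weighted decelerator-bound).
    """
    if y0 is None:
        y0 = chain.inducer_conc
    if y0 < 0:
        raise ValueError("inducer concentration must be >= 0")
    by_step = _group_decels(chain, decels)
    n = chain.n_steps
    qs = np.array([float(s.q) for s in chain.steps])
    xt = np.array([float(s.X_total) for s in chain.steps])
    facs = [_decel_factors(by_step.get(i + 1, ())) for i in range(n)]

    if y0 == 0.0:
        out = {}
        for i, s in enumerate(chain.steps):
            off = facs[i][0]
            out[s.index] = (xt[i] / (1.0 + off), 0.0)
        return out

    def forward(x_free: np.ndarray):
        """Products given free accelerator concentrations."""
        y_star = np.empty(n)
        y_eff = np.empty(n)
        y_mass = np.empty(n)
        y_prev = y0
        for i in range(n):
            off, pb, tm, mm = facs[i]
            y_star[i] = qs[i] * x_free[i] * y_prev
            y_eff[i] = y_star[i] * tm
            y_mass[i] = y_star[i] * mm  # free + decelerator-bound product
            y_prev = y_eff[i]
        return y_star, y_eff, y_mass

    def residual(u: np.ndarray):
        x_free = np.exp(u)
        _, _, y_mass = forward(x_free)
        res = np.empty(n)
        tail = np.cumsum(y_mass[::-1])[::-1]  # sum_{j>=i} mass_j
        for i in range(n):
            off = facs[i][0]
            res[i] = (x_free[i] * (1.0 + off) + tail[i] - xt[i]) / max(xt[i], 1e-300)
        return res

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        if k == 0:
            x0 = xt / np.array([1.0 + f[0] for f in facs]) * 0.5
        elif k == 1:
            x0 = xt / np.array([1.0 + f[0] for f in facs]) * 0.99
        else:
            x0 = xt * np.exp(rng.uniform(-3, 0, size=n))
        sol = root(residual, np.log(np.maximum(x0, 1e-300)), method="hybr",
                   options={"xtol": 1e-14})
        r = float(np.max(np.abs(residual(sol.x))))
        if best is None or r < best[0]:
            best = (r, sol.x)
        if r <= rtol:
            break
    r, u = best
    if r > rtol:
        raise RuntimeError(
            f"equilibrium solver did not converge: max relative residual {r:.3e}"
        )
    x_free = np.exp(u)
    _, y_eff, _ = forward(x_free)
    return {s.index: (float(x_free[i]), float(y_eff[i]))
            for i, s in enumerate(chain.steps)}


def activity_from_solution(
    chain: ReactionChain, solution: Mapping[int, tuple[float, float]]
) -> float:
    """Total activity ``A = sum a_i [Y_i]`` from a numeric solution."""
    w = chain.weights()
    return float(sum(wi * solution[i][1] for i, wi in w.items()))


# ---------------------------------------------------------------------------
# Hill fit
# ---------------------------------------------------------------------------


def hill_fit(
    doses: np.ndarray, activities: np.ndarray
) -> tuple[float, float, float, float]:
    """Least-squares fit of the 4-parameter Hill equation.

    ``A = low + (high - low) * x^h / (K^h + x^h)``.  Returns
    ``(hill_coefficient, half_max_conc, plateau_low, plateau_high)``.
    Raises ``ValueError`` when the data carry no transition.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(activities, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 dose points")
    if np.any(x < 0):
        raise ValueError("doses must be >= 0")
    span = y.max() - y.min()
    if span <= 1e-12 * max(abs(y).max(), 1.0):
        raise ValueError("flat data: Hill exponent undefined")

    pos = x > 0
    k0 = np.exp(np.mean(np.log(x[pos]))) if pos.any() else 1.0

    def model(x, h, k, lo, hi):
        xh = np.where(x > 0, np.power(x, h), 0.0)
        return lo + (hi - lo) * xh / (np.power(k, h) + xh)

    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    p0 = [1.0, k0, y.min() if increasing else y.max(),
          y.max() if increasing else y.min()]
    popt, _ = curve_fit(
        model, x, y, p0=p0,
        bounds=([0.05, 1e-12, -np.inf, -np.inf], [20.0, 1e12, np.inf, np.inf]),
        maxfev=20000,
    )
    h, k, lo, hi = popt
    return float(h), float(k), float(lo), float(hi)


# ---------------------------------------------------------------------------
# irreversible "hit-and-run" equivalence
# ---------------------------------------------------------------------------


def hit_and_run_steady_state(
    scheme_kind: str,
    kf: float,
    kr: float,
    totals: Mapping[str, float],
    upstream_conc: float,
    kf2: float = 0.0,
    kr2: float = 1.0,
    tol: float = 1e-10,
) -> float:
    """Steady state of the irreversible hit-and-run ODEs by integration.

    ``scheme_kind='post-CLS-like'``: ``P + X -> P' + X``, ``P' -> P`` with
    conserved ``P^T`` and fixed ``X^T = upstream-independent`` accelerator;
    the steady state equals the reversible form ``q X^T P^T / (1 + q X^T)``
    with ``q = kf/kr``.

    ``scheme_kind='CLS-like'``: ``P + X -> X' + P``, ``X' -> X`` optionally
    followed by ``X' + U -> X'' + U``, ``X'' -> X'`` (rates kf2/kr2,
    ``q' = kf2/kr2``); the steady state of ``[X']`` equals
    ``q X^T [P] / (1 + q [P] + q q' U^T [P])``.
    """
    if kf <= 0 or kr <= 0:
        raise ValueError("rates must be > 0")
    if scheme_kind == "post-CLS-like":
        XT = float(totals["X"])
        PT = float(totals["P"])

        def rhs(_t, s):
            pprime = s[0]
            return [kf * (PT - pprime) * XT - kr * pprime]

        sol = solve_ivp(rhs, (0.0, 200.0 / min(kr, kf * XT + kr)), [0.0],
                        rtol=tol, atol=tol * max(PT, 1.0))
        return float(sol.y[0, -1])
    if scheme_kind == "CLS-like":
        if kf2 < 0 or kr2 <= 0:
            raise ValueError("rates must be > 0")
        XT = float(totals["X"])
        UT = float(totals.get("U", 0.0))
        P = float(upstream_conc)

        def rhs(_t, s):
            xp, xpp = s
            x = XT - xp - xpp
            return [
                kf * P * x - kr * xp - kf2 * xp * UT + kr2 * xpp,
                kf2 * xp * UT - kr2 * xpp,
            ]

        tmax = 200.0 / min(kr, kr2)
        sol = solve_ivp(rhs, (0.0, tmax), [0.0, 0.0], rtol=tol,
                        atol=tol * max(XT, 1.0), method="LSODA")
        return float(sol.y[0, -1])
    raise ValueError(f"unknown scheme_kind {scheme_kind!r}")


# ---------------------------------------------------------------------------
# oligomeric accelerator
# ---------------------------------------------------------------------------


def oligomer_effective_step(olig: OligomerSpec, q, X_total, y_prev):
    """Effective product of a step whose accelerator acts via an oligomer.

    The accelerator X first binds a superabundant partner Z (affinity r);
    the complex then drives the step with affinity q.  Monotone increasing
    and saturating in [Z]; at saturation it reduces to a plain accelerator
    step ``q X^T y / (1 + q y)``.
    """
    w = olig.r * olig.Z_total / (1 + olig.r * olig.Z_total)
    return q * X_total * w * y_prev / (1 + q * w * y_prev)
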