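"""Plot-signature rule engine and receptor-position feasibility analysis.

Two complementary inference routes:

* :func:`classify` fires the 22-entry qualitative rule table (shipped as
  ``data/plot_rules.yaml``) against a :class:`PlotSignature` and intersects
  the fired predictions over a fine-grained configuration space.
* :func:`feasibility_scan` asks, for a concrete configuration, whether any
  positive parameter assignment of its derived dose-response-parameter
  forms can reproduce a required sign pattern — analytically for the six
  hand-analysed receptor-location cases, and by a vectorized stochastic
  scan for all configurations.

:func:`infer_gr_action` intersects feasibility across cofactors to localize
the receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .config_formulas import (
    ACCELERATOR,
    DECELERATOR,
    DECEL_TYPES,
    Configuration,
    Mechanism,
    enumerate_configurations,
    numeric_form_functions,
)

__all__ = [
    "PlotSignature",
    "Prediction",
    "SignPattern",
    "FeasibilityResult",
    "classify",
    "load_rules",
    "feasibility_scan",
    "infer_gr_action",
    "TIF2_PATTERN",
]


# ---------------------------------------------------------------------------
# signature and pattern types
# ---------------------------------------------------------------------------


@dataclass
class PlotSignature:
    """Qualitative feature set of the four parameter plots vs one cofactor."""

    directions: dict[str, str | None] = field(default_factory=dict)
    # per-parameter shape flags, keyed like 'amax_linear_origin'
    shapes: dict[str, bool] = field(default_factory=dict)
    h_amin_vs_amax: str = "unknown"        # '<' | '>' | '=' | 'unknown'
    h_recip_amin_vs_amax: str = "unknown"
    amax_gt_amin: bool | None = None

    def features(self) -> dict:
        f = {}
        for p in ("amax", "amin", "ic50", "ratio"):
            f[f"{p}_dir"] = self.directions.get(p)
        f.update(self.shapes)
        f["h_amin_vs_amax"] = self.h_amin_vs_amax
        f["h_recip_amin_vs_amax"] = self.h_recip_amin_vs_amax
        return f


@dataclass(frozen=True)
class SignPattern:
    """Required directions (None = unconstrained) plus ordering constraints."""

    amax: str | None = None
    amin: str | None = None
    ic50: str | None = None
    ratio: str | None = None
    require_amax_gt_amin: bool = True
    h_amin_vs_amax: str | None = None
    h_recip_amin_vs_amax: str | None = None

    @classmethod
    def from_signature(
        cls, sig: PlotSignature, use_orderings: bool = False
    ) -> "SignPattern":
        """Directions become constraints; 'const' is non-informative."""

        def req(p):
            d = sig.directions.get(p)
            return d if d in ("inc", "dec") else None

        kw = {}
        if use_orderings:
            if sig.h_amin_vs_amax in ("<", ">"):
                kw["h_amin_vs_amax"] = sig.h_amin_vs_amax
            if sig.h_recip_amin_vs_amax in ("<", ">"):
                kw["h_recip_amin_vs_amax"] = sig.h_recip_amin_vs_amax
        return cls(
            amax=req("amax"), amin=req("amin"),
            ic50=req("ic50"), ratio=req("ratio"),
            **kw,
        )


#: the repression pattern observed for a coactivator-like cofactor:
#: A_max up, everything else down, with A_max > A_min throughout.
TIF2_PATTERN = SignPattern(amax="inc", amin="dec", ic50="dec", ratio="dec")


# ---------------------------------------------------------------------------
# rule table
# ---------------------------------------------------------------------------

_ATOMIC_MECHS = ("A",) + DECEL_TYPES

_MECH_CLASS = {
    "A": {"A"},
    "D": set(DECEL_TYPES),
    "C": {"LC", "PC"},
    "U": {"LU", "PU"},
    "N": {"LN", "PN"},
    "L": {"LC", "LU", "LN"},
    "P": {"PC", "PU", "PN"},
    **{t: {t} for t in DECEL_TYPES},
}


def _expand_mech(spec) -> set[str]:
    if spec == "any":
        return set(_ATOMIC_MECHS)
    out: set[str] = set()
    for code in spec:
        out |= _MECH_CLASS[code]
    return out


def _expand(spec, universe) -> set[str]:
    if spec == "any":
        return set(universe)
    return set(spec)


@dataclass(frozen=True)
class Rule:
    entry: int
    when: tuple[tuple[str, object], ...]
    predictions: tuple[tuple, ...]  # (f_mechs, f_pos, gr_mechs, gr_pos, rels)
    text: str

    def fires(self, sig: PlotSignature) -> bool:
        f = sig.features()
        for key, want in self.when:
            have = f.get(key)
            if have is None or have != want:
                return False
        return True


def load_rules() -> list[Rule]:
    raw = yaml.safe_load(
        resources.files("clskinetics.data").joinpath("plot_rules.yaml").read_text()
    )
    rules = []
    for e in raw["entries"]:
        preds = []
        for p in e["predictions"]:
            preds.append(
                (
                    frozenset(_expand_mech(p["f_mech"])),
                    frozenset(_expand(p["f_pos"], ("before", "at", "after"))),
                    frozenset(_expand_mech(p["gr_mech"])),
                    frozenset(_expand(p["gr_pos"], ("before", "at", "after"))),
                    frozenset(
                        _expand(p["rel"], ("GR-before-F", "GR-after-F", "same-step"))
                    ),
                )
            )
        rules.append(
            Rule(
                entry=e["id"],
                when=tuple(sorted(e["when"].items())),
                predictions=tuple(preds),
                text=e["text"],
            )
        )
    return rules


_RULES: list[Rule] | None = None


def _rules() -> list[Rule]:
    global _RULES
    if _RULES is None:
        _RULES = load_rules()
    return _RULES


# fine-grained configuration space for rule intersection --------------------


@dataclass(frozen=True)
class FineConfig:
    f_mech: str   # atomic: 'A' or two-letter decelerator code
    f_pos: str
    gr_mech: str
    gr_pos: str
    rel: str      # 'GR-before-F' | 'GR-after-F' | 'same-step'


def fine_configuration_space() -> list[FineConfig]:
    """Atomic-mechanism expansion of the admissible configuration space."""
    out = []
    positions = ("before", "at", "after")
    for f_pos in positions:
        for gr_pos in positions:
            for f_mech in _ATOMIC_MECHS:
                for gr_mech in _ATOMIC_MECHS:
                    if gr_mech == "A" and gr_pos != "after":
                        continue  # GR cannot repress as a pre/at-CLS accelerator
                    pf, pg = positions.index(f_pos), positions.index(gr_pos)
                    if pf == pg:
                        rels = ["same-step"]
                        if f_pos != "at":
                            rels += ["GR-before-F", "GR-after-F"]
                    else:
                        rels = ["GR-before-F" if pg < pf else "GR-after-F"]
                    for rel in rels:
                        if rel == "same-step":
                            kinds = {f_mech == "A", gr_mech == "A"}
                            if kinds != {True, False}:
                                continue  # one accelerator, one decelerator
                        out.append(FineConfig(f_mech, f_pos, gr_mech, gr_pos, rel))
    return out


@dataclass
class Prediction:
    """One fired rule entry with its structural constraints."""

    entry: int
    text: str
    alternatives: tuple
    matched: set[FineConfig] = field(default_factory=set)


def classify(sig: PlotSignature) -> tuple[list[Prediction], set[FineConfig]]:
    """Fire every matching rule entry; report the consistent intersection.

    Returns ``(predictions, intersection)`` where each prediction carries
    its entry number and the set of fine-grained configurations matching
    any of its alternatives, and ``intersection`` is the conjunction over
    all fired entries (empty when the signature is contradictory).
    """
    space = fine_configuration_space()
    fired: list[Prediction] = []
    for rule in _rules():
        if not rule.fires(sig):
            continue
        matched = set()
        for f_mechs, f_pos, gr_mechs, gr_pos, rels in rule.predictions:
            for fc in space:
                if (
                    fc.f_mech in f_mechs
                    and fc.f_pos in f_pos
                    and fc.gr_mech in gr_mechs
                    and fc.gr_pos in gr_pos
                    and fc.rel in rels
                ):
                    matched.add(fc)
        fired.append(
            Prediction(
                entry=rule.entry, text=rule.text,
                alternatives=rule.predictions, matched=matched,
            )
        )
    if fired:
        inter = set.intersection(*(p.matched for p in fired))
    else:
        inter = set(space)
    return fired, inter


# ---------------------------------------------------------------------------
# feasibility of a configuration under a sign pattern
# ---------------------------------------------------------------------------


@dataclass
class FeasibilityResult:
    feasible: bool
    witness: dict[str, float] | None
    analytic_verdict: bool | None
    n_samples: int


def _analytic_verdict(config: Configuration, pattern: SignPattern) -> bool | None:
    """Hard-coded inequality logic for the six hand-analysed cases.

    Defined only against the canonical repression pattern (A_max up;
    A_min, IC50 and ratio down; A_max > A_min) for a cofactor acting as an
    accelerator after the CLS.
    """
    if pattern != TIF2_PATTERN:
        return None
    if config.factor_mech.kind != "accelerator" or config.factor_pos != "after":
        return None
    gm, gp, rel = config.gr_mech, config.gr_pos, config.order
    if gm.kind == "decelerator" and gp == "before" and rel != "same-step":
        # ratio is constant in the cofactor: cannot decrease
        return False
    if gm.kind == "decelerator" and gp == "at":
        # A_max-up and A_min-down inequalities are jointly unsatisfiable
        return False
    if gm.kind == "accelerator" and rel == "GR-before-F":
        # A_max does not depend on the cofactor: cannot increase
        return False
    if (
        gm.kind == "decelerator"
        and gm.decel_type in ("LC", "PC")
        and gp == "after"
        and rel == "GR-before-F"
    ):
        # competitive decelerator between the CLS and the cofactor:
        # the A_max/A_min inequalities cannot hold for positive parameters
        return False
    if gm.kind == "accelerator" and rel == "GR-after-F":
        return True
    if (
        gm.kind == "decelerator"
        and gm.decel_type in ("LC", "PC")
        and gp == "after"
        and rel == "GR-after-F"
    ):
        # IC50 strictly increases whenever the accelerator-binding arm is
        # active: the IC50-decreasing requirement is unsatisfiable
        return False
    return None


def _sample_parameters(
    names: Sequence[str], n: int, rng: np.random.Generator,
    g_sweep: Sequence[float] = (1.0, 10.0, 100.0),
) -> np.ndarray:
    """Log-uniform positive draws; G swept over decades; beta in [0, 1]."""
    vals = np.empty((len(names), n))
    for i, name in enumerate(names):
        if name == "G":
            vals[i] = rng.choice(np.asarray(g_sweep), size=n)
        elif name.startswith("beta"):
            vals[i] = rng.uniform(0.0, 1.0, size=n)
        else:
            vals[i] = 10.0 ** rng.uniform(-3, 3, size=n)
    return vals


def _pattern_mask(
    coeffs: Mapping[str, np.ndarray],
    pattern: SignPattern,
    x_probe: Sequence[float] = (1.0, 100.0),
) -> np.ndarray:
    """Boolean mask of samples whose parameter forms satisfy the pattern."""
    t00, t01 = coeffs["t00"], coeffs["t01"]
    tp0, tp1 = coeffs["tp0"], coeffs["tp1"]
    u00, u01 = coeffs["u00"], coeffs["u01"]
    up0, up1 = coeffs["up0"], coeffs["up1"]

    def det(num0, num1, den0, den1):
        # sign of d/dx [(num0 + num1 x)/(den0 + den1 x)]
        return num1 * den0 - num0 * den1

    dets = {
        "amax": det(t00, t01, u00, u01),
        "amin": det(tp0, tp1, up0, up1),
        "ic50": det(u00, u01, up0, up1),
        "ratio": det(t00, t01, tp0, tp1),
    }
    ok = np.ones_like(t00, dtype=bool)
    for p in ("amax", "amin", "ic50", "ratio"):
        want = getattr(pattern, p)
        if want == "inc":
            ok &= dets[p] > 0
        elif want == "dec":
            ok &= dets[p] < 0
    if pattern.require_amax_gt_amin:
        for x in x_probe:
            amax = (t00 + t01 * x) / (u00 + u01 * x)
            amin = (tp0 + tp1 * x) / (up0 + up1 * x)
            ok &= amax > amin
    if pattern.h_amin_vs_amax in ("<", ">"):
        with np.errstate(divide="ignore", invalid="ignore"):
            h_amax = np.where(u01 > 0, u00 / u01, np.inf)
            h_amin = np.where(up1 > 0, up0 / up1, np.inf)
        cmp = h_amin < h_amax if pattern.h_amin_vs_amax == "<" else h_amin > h_amax
        ok &= cmp
    if pattern.h_recip_amin_vs_amax in ("<", ">"):
        with np.errstate(divide="ignore", invalid="ignore"):
            r_amax = np.where(t01 > 0, t00 / t01, np.inf)
            r_amin = np.where(tp1 > 0, tp0 / tp1, np.inf)
        cmp = (
            r_amin < r_amax
            if pattern.h_recip_amin_vs_amax == "<"
            else r_amin > r_amax
        )
        ok &= cmp
    return ok


def feasibility_scan(
    config: Configuration,
    pattern: SignPattern,
    n_samples: int = 10_000,
    seed: int = 0,
    batch: int = 20_000,
) -> FeasibilityResult:
    """Can any positive parameter assignment realize the sign pattern?

    Dual verdicts: analytic (hard-coded inequality logic where available)
    and stochastic (log-uniform positive parameter draws over [1e-3, 1e3],
    receptor scale G swept over {1, 10, 100}).  The first witness found is
    returned.
    """
    names, fn = numeric_form_functions(config)
    rng = np.random.default_rng(seed)
    analytic = _analytic_verdict(config, pattern)
    witness = None
    remaining = n_samples
    while remaining > 0:
        m = min(batch, remaining)
        vals = _sample_parameters(names, m, rng)
        with np.errstate(over="ignore", invalid="ignore"):
            coeffs = fn(vals)
            ok = _pattern_mask(coeffs, pattern)
        idx = np.nonzero(ok)[0]
        if idx.size:
            witness = {nm: float(vals[i, idx[0]]) for i, nm in enumerate(names)}
            break
        remaining -= m
    # the analytic verdict, when defined, is authoritative; the stochastic
    # scan backs it with a witness (their agreement is a tested invariant)
    feasible = (witness is not None) if analytic is None else analytic
    return FeasibilityResult(
        feasible=feasible,
        witness=witness,
        analytic_verdict=analytic,
        n_samples=n_samples,
    )


def _coarse_matches_fine(cfg: Configuration, fc: FineConfig) -> bool:
    if (fc.f_pos, fc.gr_pos, fc.rel) != (cfg.factor_pos, cfg.gr_pos, cfg.order):
        return False
    f_ok = (fc.f_mech == "A") == (cfg.factor_mech.kind == "accelerator")
    g_ok = (fc.gr_mech == "A") == (cfg.gr_mech.kind == "accelerator")
    return f_ok and g_ok


def _subtype_choices(allowed: set[str]) -> list[str | None]:
    """Representative decelerator subtypes to scan (None = generic)."""
    decel = sorted(allowed & set(DECEL_TYPES))
    if not decel:
        return []
    if len(decel) == len(DECEL_TYPES):
        return [None]
    return decel


def infer_gr_action(
    signatures: Mapping[str, PlotSignature],
    configs: Sequence[Configuration] | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
    use_orderings: bool = False,
    full_decel_space: bool = False,
) -> dict:
    """Intersect per-cofactor feasibility to localize the receptor.

    A configuration survives a cofactor when a feasibility scan finds its
    observed sign pattern attainable ('const' directions are treated as
    non-informative).  Survivors must pass for every cofactor; cofactors
    whose row is all-feasible are reported as non-informative.  Post-CLS
    decelerators are scanned as competitive types unless
    ``full_decel_space`` is set.
    """
    if not signatures:
        raise ValueError("need at least one cofactor signature")
    if configs is None:
        configs = enumerate_configurations()

    per_cofactor = {
        name: SignPattern.from_signature(sig, use_orderings=use_orderings)
        for name, sig in sorted(signatures.items())
    }

    def decel_choices(pos: str) -> list[str | None]:
        # after the CLS only the competitive decelerator types are scanned,
        # mirroring the printed case analysis: post-CLS products are trace
        # species, so a decelerator acts there by binding the accelerator
        if pos == "after" and not full_decel_space:
            return ["LC", "PC"]
        return [None]

    matrix: dict[str, dict[str, bool]] = {c.id: {} for c in configs}
    for k, cfg in enumerate(configs):
        f_choices = (
            decel_choices(cfg.factor_pos)
            if cfg.factor_mech.kind == "decelerator"
            else [None]
        )
        g_choices = (
            decel_choices(cfg.gr_pos)
            if cfg.gr_mech.kind == "decelerator"
            else [None]
        )
        for j, (name, pattern) in enumerate(per_cofactor.items()):
            feasible = False
            for ft in f_choices:
                for gt in g_choices:
                    res = feasibility_scan(
                        cfg.with_types(factor_type=ft, gr_type=gt),
                        pattern,
                        n_samples=n_samples,
                        seed=seed + 1000 * k + j,
                    )
                    if res.feasible:
                        feasible = True
                        break
                if feasible:
                    break
            matrix[cfg.id][name] = feasible

    survivors = [c for c in configs if all(matrix[c.id].values())]
    uninformative = [
        name for name in signatures if all(matrix[c.id][name] for c in configs)
    ]
    out = {
        "survivors": survivors,
        "matrix": matrix,
        "uninformative_cofactors": uninformative,
    }
    if not survivors:
        out["diagnosis"] = (
            "no configuration is consistent with all cofactor signatures: "
            "the data contradict the model class"
        )
    return out
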