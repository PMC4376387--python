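"""Shared fixtures: canonical chains, configurations and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from clskinetics.config_formulas import (
    ACCELERATOR,
    DECELERATOR,
    Configuration,
)
from clskinetics.kinetic_core import (
    DeceleratorSpec,
    ReactionChain,
    ReactionStep,
)


@pytest.fixture
def three_step_chain() -> ReactionChain:
    """The worked 3-reaction chain: q=(1, 0.01, 1), X_total=(1,1,1), CLS=2."""
    return ReactionChain(
        steps=[
            ReactionStep(1, 1.0, 1.0),
            ReactionStep(2, 0.01, 1.0),
            ReactionStep(3, 1.0, 1.0),
        ],
        cls_index=2,
        activity_weights={3: 1.0},
    )


@pytest.fixture
def case5_config() -> Configuration:
    """Cofactor accelerates after the CLS; receptor accelerates after it."""
    return Configuration(ACCELERATOR, "after", ACCELERATOR, "after", "GR-after-F")


def random_cls_chain(
    rng: np.random.Generator,
    n_steps: int | None = None,
    eps: float = 1e-3,
    with_decels: bool = False,
) -> tuple[ReactionChain, list[DeceleratorSpec]]:
    """A random chain satisfying the CLS regime at threshold ``eps``.

    Steps 2..cls carry limited accelerators (q*X_total <= eps); post-CLS
    accelerators are in excess of the (tiny) product flux.
    """
    if n_steps is None:
        n_steps = int(rng.integers(2, 6))
    cls = int(rng.integers(2, n_steps + 1))
    steps = []
    for i in range(1, n_steps + 1):
        if 2 <= i <= cls:
            q = float(10 ** rng.uniform(-1, 1))
            xt = eps * float(rng.uniform(0.1, 1.0)) / q
        elif i == 1:
            q = float(10 ** rng.uniform(-1, 1))
            xt = float(10 ** rng.uniform(-1, 1))
        else:  # post-CLS: moderate transfer, accelerator in excess
            q = float(rng.uniform(0.1, 2.0))
            xt = float(rng.uniform(0.5, 5.0))
        steps.append(ReactionStep(i, q, xt))
    chain = ReactionChain(steps, cls_index=cls)
    decels = []
    if with_decels and n_steps >= 1:
        step = int(rng.integers(1, n_steps + 1))
        decels.append(
            DeceleratorSpec(
                step=step,
                conc=float(10 ** rng.uniform(-1, 1)),
                q_prime=float(10 ** rng.uniform(-1, 1)),
                alpha=float(rng.choice([0.0, 1.0])),
                beta=float(rng.uniform(0, 1)),
                gamma=float(rng.choice([0.0, 1.0])),
            )
        )
    return chain, decels
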