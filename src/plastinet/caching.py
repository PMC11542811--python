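"""Two-compartment plasticity: cheap transient changes, costly consolidation.

Each synapse carries a transient component ``w_trans`` (decaying, cheap to
maintain) and a persistent component ``w_pers``; the effective connection
strength is their sum.  Proposed updates land in the transient component; when
``|w_trans|`` reaches the threshold ``theta`` the transient amount is added to
the persistent weight and reset to zero.  Only consolidation events are
charged to the m0/m1 accumulators; maintaining the transient compartment
costs ``c * sum |w_trans|`` per sample presentation and never counts toward m0.

Per-sample operation order is fixed as decay -> update -> consolidate ->
charge upkeep.  This order makes ``theta = 0`` exactly equivalent to plain
training (the transient compartment is empty entering every step), which the
ledger identities rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyLedger
from .network import MLPWeights, ShapeError, UpdateProposal


@dataclass(frozen=True)
class CachingConfig:
    """Threshold / decay / upkeep-cost parameters of the caching rule."""

    theta: float = 0.05
    lambda_decay: float = 1e-3
    c: float = 0.01

    def __post_init__(self) -> None:
        if self.theta < 0 or self.lambda_decay < 0 or self.c < 0:
            raise ValueError("theta, lambda_decay and c must all be >= 0")
        if self.lambda_decay > 1:
            raise ValueError("lambda_decay is a per-sample rate in [0, 1]")


class CacheState:
    """Transient and persistent weight components for both layers."""

    def __init__(self, weights: MLPWeights, config: CachingConfig):
        self.config = config
        # Initial weights are taken as already-persistent structure.
        self.pers = {"in": weights.W_in.copy(), "out": weights.W_out.copy()}
        self.trans = {"in": np.zeros_like(weights.W_in), "out": np.zeros_like(weights.W_out)}

    def effective(self, layer: str) -> np.ndarray:
        return self.pers[layer] + self.trans[layer]

    def write_effective(self, weights: MLPWeights) -> None:
        """Refresh the forward-pass weights to ``w_pers + w_trans``."""
        np.add(self.pers["in"], self.trans["in"], out=weights.W_in)
        np.add(self.pers["out"], self.trans["out"], out=weights.W_out)


def caching_step(cache: CacheState, restricted: UpdateProposal, ledger: EnergyLedger) -> None:
    """One sample presentation of the caching rule.

    Per layer: (1) decay the transient component, (2) add the restricted
    deltas, (3) consolidate every entry whose ``|w_trans|`` reached theta
    (charging the consolidated amount as an applied update), (4) charge
    transient upkeep on what remains.
    """
    cfg = cache.config
    for layer, deltas in (("in", restricted.dW_in), ("out", restricted.dW_out)):
        trans = cache.trans[layer]
        if deltas.shape != trans.shape:
            raise ShapeError(f"delta shape {deltas.shape} != cache shape {trans.shape}")
        if cfg.lambda_decay:
            trans *= 1.0 - cfg.lambda_decay
        trans += deltas
        if not np.isfinite(trans).all():
            raise FloatingPointError("non-finite transient weights")
        hit = (np.abs(trans) >= cfg.theta) & (trans != 0.0)
        if hit.any():
            consolidated = np.where(hit, trans, 0.0)
            ledger.charge_update(consolidated, layer)
            cache.pers[layer] += consolidated
            trans[hit] = 0.0
        ledger.charge_transient(trans, cfg.c, layer)
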