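"""Metabolic cost accounting for synaptic updates.

The cost of modifying one synapse by ``dw`` is taken to be ``|dw| ** alpha``;
total cost sums over synapses and time steps under an independence assumption
(no spatial or temporal interaction between plasticity events).  Two limits
are tracked explicitly:

* ``m0`` — the number of nonzero applied updates (the alpha -> 0 limit),
  implemented as an exact count rather than a numeric limit.  An exact-zero
  test decides whether a synapse was updated; with zero-meaned inputs
  accidental exact zeros do not occur.
* ``m1`` — the accumulated absolute weight change, sum of |dw|.

Arbitrary intermediate exponents can be tracked via ``track_alphas``.  Under
two-compartment (transient/persistent) plasticity, consolidation events are
charged through :meth:`EnergyLedger.charge_update` while the upkeep of the
transient compartment is charged through
:meth:`EnergyLedger.charge_transient`; transient upkeep never contributes
to ``m0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LayerAccount:
    """Per-layer accumulators."""

    m0: int = 0
    m1: float = 0.0
    m_alpha: dict[float, float] = field(default_factory=dict)
    transient_cost: float = 0.0


class EnergyLedger:
    """Running energy accumulators, split per layer.

    Parameters
    ----------
    track_alphas : iterable of float
        Extra exponents alpha > 0 to accumulate sum |dw|^alpha for.
    potentiation_only : bool
        Charge only positive weight changes (cost-asymmetry variant).
    """

    def __init__(self, track_alphas: tuple[float, ...] = (), potentiation_only: bool = False):
        for a in track_alphas:
            if not a > 0:
                raise ValueError("tracked alphas must be > 0")
        self.track_alphas = tuple(track_alphas)
        self.potentiation_only = bool(potentiation_only)
        self.layers: dict[str, LayerAccount] = {}

    def _account(self, layer_id: str) -> LayerAccount:
        if layer_id not in self.layers:
            self.layers[layer_id] = LayerAccount(m_alpha={a: 0.0 for a in self.track_alphas})
        return self.layers[layer_id]

    # -- totals ------------------------------------------------------------

    @property
    def m0(self) -> int:
        return sum(acc.m0 for acc in self.layers.values())

    @property
    def m1(self) -> float:
        return sum(acc.m1 for acc in self.layers.values())

    @property
    def transient_cost(self) -> float:
        return sum(acc.transient_cost for acc in self.layers.values())

    def m_alpha(self, alpha: float) -> float:
        return sum(acc.m_alpha.get(alpha, 0.0) for acc in self.layers.values())

    @property
    def m1_total(self) -> float:
        """M1 energy including transient maintenance."""
        return self.m1 + self.transient_cost

    # -- charging ----------------------------------------------------------

    def charge_update(self, applied_deltas: np.ndarray, layer_id: str) -> "EnergyLedger":
        """Charge one batch of applied weight changes to ``layer_id``.

        Increments ``m0`` by the number of exactly-nonzero entries, ``m1`` by
        the sum of absolute changes, and each tracked alpha accumulator by
        sum over nonzero entries of ``|dw|^alpha``.
        """
        d = np.asarray(applied_deltas, dtype=np.float64)
        if self.potentiation_only:
            d = np.where(d > 0, d, 0.0)
        absd = np.abs(d)
        s = float(absd.sum())
        if not np.isfinite(s):
            raise FloatingPointError(f"non-finite deltas charged to layer {layer_id!r}")
        acc = self._account(layer_id)
        acc.m0 += int(np.count_nonzero(d))
        acc.m1 += s
        if self.track_alphas:
            nz = absd[absd != 0]
            for a in self.track_alphas:
                acc.m_alpha[a] += float((nz**a).sum())
        return self

    def charge_transient(self, transient_weights: np.ndarray, c: float, layer_id: str = "in") -> "EnergyLedger":
        """Charge transient-compartment upkeep ``c * sum |w_trans|``; leaves m0 alone."""
        if c < 0:
            raise ValueError("transient cost constant c must be >= 0")
        if c == 0:
            return self
        self._account(layer_id).transient_cost += c * float(np.abs(transient_weights).sum())
        return self

    # -- export ------------------------------------------------------------

    def totals(self) -> dict:
        """Flat snapshot of totals and per-layer breakdown (for run logs)."""
        row: dict[str, float] = {
            "m0": self.m0,
            "m1": self.m1,
            "transient_cost": self.transient_cost,
        }
        for a in self.track_alphas:
            row[f"m_alpha_{a:g}"] = self.m_alpha(a)
        for layer_id, acc in sorted(self.layers.items()):
            row[f"m0_{layer_id}"] = acc.m0
            row[f"m1_{layer_id}"] = acc.m1
            row[f"transient_cost_{layer_id}"] = acc.transient_cost
        return row
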