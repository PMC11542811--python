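"""Restriction operators: which proposed synaptic changes are actually applied.

Variants
--------
``full``
    Identity: apply every proposed change (vanilla backprop).
``dropconnect``
    A fresh Bernoulli mask per sample (optionally one persistent mask per
    output class, drawn on first use).
``fixed_synapse_mask``
    Bernoulli masks over both weight arrays, drawn once and fixed for the run.
``fixed_neuron_mask``
    A fixed subset of hidden units keeps plastic *incoming* synapses; the
    back-propagated error of the other units is silenced.  Outgoing synapses
    stay fully plastic.
``subnet``
    Coordinated plasticity: incoming AND outgoing synapses of a fixed subset
    of hidden units are plastic, everything else frozen — a plastic
    sub-network embedded in a static network.
``topk``
    Competitive selection recomputed every sample: keep only the
    largest-magnitude proposed changes in the input-to-hidden layer (per layer
    or per hidden unit); hidden-to-output changes are always applied.  When a
    subnet is also configured, selection runs inside the subnet only.
    Exploratory ``selection_metric`` settings instead keep whole rows for the
    hidden units with the largest back-propagated error or activation.

Top-k tie-breaking is deterministic: entries strictly above the magnitude
threshold are kept, ties at the threshold are filled in ascending flat-index
order so that exactly ``ceil(fraction * n)`` entries survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .network import ShapeError, UpdateProposal

VARIANTS = ("full", "dropconnect", "fixed_synapse_mask", "fixed_neuron_mask", "subnet", "topk")


@dataclass(frozen=True)
class StrategySpec:
    """Configuration of a plasticity-restriction strategy."""

    variant: str = "full"
    f0: float = 1.0  # plastic fraction, input-to-hidden layer
    f1: float = 1.0  # plastic fraction, hidden-to-output layer
    subnet_size: int | None = None
    topk_fraction: float = 1.0
    topk_scope: str = "layer"  # or "neuron"
    per_class: bool = False
    selection_metric: str = "update_magnitude"  # or "neuron_error", "neuron_activity"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown strategy variant {self.variant!r}")
        for name, f in (("f0", self.f0), ("f1", self.f1), ("topk_fraction", self.topk_fraction)):
            if not (0 < f <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {f}")
        if self.topk_scope not in ("layer", "neuron"):
            raise ValueError(f"unknown topk_scope {self.topk_scope!r}")
        if self.selection_metric not in ("update_magnitude", "neuron_error", "neuron_activity"):
            raise ValueError(f"unknown selection_metric {self.selection_metric!r}")
        if self.subnet_size is not None and self.subnet_size < 1:
            raise ValueError("subnet_size must be >= 1")


@dataclass
class StrategyState:
    """Per-run state: fixed masks / plastic unit set / rng stream."""

    spec: StrategySpec
    rng: np.random.Generator
    fixed_mask_in: np.ndarray | None = None
    fixed_mask_out: np.ndarray | None = None
    plastic_neuron_set: np.ndarray | None = None
    class_masks: dict = field(default_factory=dict)


def init_strategy(
    spec: StrategySpec, shapes: tuple[tuple[int, int], tuple[int, int]], rng: np.random.Generator
) -> StrategyState:
    """Draw the fixed structure (masks / subnet) for a run; deterministic given rng."""
    shape_in, shape_out = shapes
    n_hidden = shape_in[0]
    state = StrategyState(spec=spec, rng=rng)
    if spec.variant == "fixed_synapse_mask":
        state.fixed_mask_in = (rng.random(shape_in) < spec.f0).astype(np.float64)
        state.fixed_mask_out = (rng.random(shape_out) < spec.f1).astype(np.float64)
    elif spec.variant in ("fixed_neuron_mask", "subnet") or (
        spec.variant == "topk" and spec.subnet_size is not None
    ):
        size = spec.subnet_size
        if size is None:
            raise ValueError(f"{spec.variant} requires subnet_size")
        if size > n_hidden:
            raise ValueError(f"subnet_size {size} exceeds {n_hidden} hidden units")
        state.plastic_neuron_set = np.sort(rng.choice(n_hidden, size=size, replace=False))
    return state


def _topk_flat_mask(absvals: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask keeping exactly k entries: all > threshold, ties by lowest index."""
    flat = absvals.ravel()
    n = flat.size
    if k >= n:
        return np.ones_like(absvals, dtype=bool)
    thresh = np.partition(flat, n - k)[n - k]
    keep = flat > thresh
    short = k - int(keep.sum())
    if short > 0:
        tie_idx = np.flatnonzero(flat == thresh)[:short]
        keep[tie_idx] = True
    return keep.reshape(absvals.shape)


def _topk_row_mask(absvals: np.ndarray, k: int) -> np.ndarray:
    """Per-row version of :func:`_topk_flat_mask` (same tie rule within each row)."""
    n = absvals.shape[1]
    if k >= n:
        return np.ones_like(absvals, dtype=bool)
    thresh = np.partition(absvals, n - k, axis=1)[:, n - k : n - k + 1]
    keep = absvals > thresh
    need = k - keep.sum(axis=1, keepdims=True)
    at = absvals == thresh
    keep |= at & (np.cumsum(at, axis=1) <= need)
    return keep


def restrict_proposal(
    state: StrategyState,
    proposal: UpdateProposal,
    sample_label: int | None = None,
    hidden_errors: np.ndarray | None = None,
    hidden_activities: np.ndarray | None = None,
) -> UpdateProposal:
    """Zero out the disallowed entries of a proposal, in place, and return it.

    For fixed variants the zeroed coordinate set is constant over the run; for
    ``dropconnect``/``topk`` it is recomputed per call.
    """
    spec = state.spec
    dW_in, dW_out = proposal.dW_in, proposal.dW_out
    n_hidden = dW_in.shape[0]
    if dW_out.shape[1] != n_hidden + 1:
        raise ShapeError("proposal layer shapes are inconsistent")

    if spec.variant == "full":
        return proposal

    if spec.variant == "dropconnect":
        # Both layers share the fraction f0 for this variant.
        if spec.per_class:
            if sample_label is None:
                raise ValueError("per-class dropconnect needs the sample label")
            if sample_label not in state.class_masks:
                state.class_masks[sample_label] = (
                    (state.rng.random(dW_in.shape) < spec.f0).astype(np.float64),
                    (state.rng.random(dW_out.shape) < spec.f0).astype(np.float64),
                )
            m_in, m_out = state.class_masks[sample_label]
        else:
            m_in = state.rng.random(dW_in.shape) < spec.f0
            m_out = state.rng.random(dW_out.shape) < spec.f0
        dW_in *= m_in
        dW_out *= m_out
        return proposal

    if spec.variant == "fixed_synapse_mask":
        dW_in *= state.fixed_mask_in
        dW_out *= state.fixed_mask_out
        return proposal

    if spec.variant == "fixed_neuron_mask":
        frozen = np.ones(n_hidden, dtype=bool)
        frozen[state.plastic_neuron_set] = False
        dW_in[frozen, :] = 0.0
        return proposal

    if spec.variant == "subnet":
        frozen = np.ones(n_hidden, dtype=bool)
        frozen[state.plastic_neuron_set] = False
        dW_in[frozen, :] = 0.0
        dW_out[:, :-1][:, frozen] = 0.0  # output bias column stays plastic
        return proposal

    # topk ------------------------------------------------------------------
    if spec.selection_metric == "update_magnitude":
        if state.plastic_neuron_set is not None:
            frozen = np.ones(n_hidden, dtype=bool)
            frozen[state.plastic_neuron_set] = False
            dW_in[frozen, :] = 0.0
            dW_out[:, :-1][:, frozen] = 0.0
            sub = dW_in[state.plastic_neuron_set, :]
            absd = np.abs(sub)
            if spec.topk_scope == "layer":
                keep = _topk_flat_mask(absd, ceil(spec.topk_fraction * absd.size))
            else:
                keep = _topk_row_mask(absd, ceil(spec.topk_fraction * absd.shape[1]))
            sub[~keep] = 0.0
            dW_in[state.plastic_neuron_set, :] = sub
        else:
            absd = np.abs(dW_in)
            if spec.topk_scope == "layer":
                keep = _topk_flat_mask(absd, ceil(spec.topk_fraction * absd.size))
            else:
                keep = _topk_row_mask(absd, ceil(spec.topk_fraction * absd.shape[1]))
            dW_in[~keep] = 0.0
        return proposal

    # exploratory neuron-level competition: keep whole rows of dW_in
    metric = hidden_errors if spec.selection_metric == "neuron_error" else hidden_activities
    if metric is None:
        raise ValueError(f"selection_metric {spec.selection_metric!r} needs the per-unit values")
    k = ceil(spec.topk_fraction * n_hidden)
    keep_rows = _topk_flat_mask(np.abs(np.asarray(metric, dtype=np.float64)), k)
    dW_in[~keep_rows, :] = 0.0
    return proposal
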