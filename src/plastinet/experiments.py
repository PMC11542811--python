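"""Criterion training runs, scaling sweeps, power-law fits and extrapolation.

``train_to_criterion`` is the single-run driver: per-sample SGD with a fresh
shuffle each epoch, a validation check every ``eval_every`` presentations, and
an energy ledger charged with exactly the deltas that were applied.  It
composes a restriction strategy (:mod:`plastinet.strategies`) and optionally
the caching rule (:mod:`plastinet.caching`).

The scaling analyses fit ``log y = log a + b log x`` by least squares and
extrapolate the fitted exponents to biologically sized networks.  The inverse
Simpson index ``q = 1 / (N * sum p_i^2)`` summarizes how evenly updates are
spread over the N synapses of a layer: q = k/N if always the same k synapses
are updated, q = 1 if updates are spread uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caching import CacheState, CachingConfig, caching_step
from .datasets import LabeledImageSet
from .energy import EnergyLedger
from .network import (
    MLPWeights,
    TrainingConfig,
    UpdateProposal,
    apply_update,
    backprop_proposal,
    evaluate_accuracy,
    forward,
    init_weights,
)
from .strategies import StrategySpec, StrategyState, init_strategy, restrict_proposal


@dataclass
class TrainRecord:
    """Outcome of one criterion-training run."""

    T: int  # sample presentations until criterion (or until stopping)
    converged: bool
    diverged: bool
    ledger: EnergyLedger
    accuracy_trace: list[tuple[int, float]]
    weights: MLPWeights
    config: TrainingConfig
    strategy: StrategySpec
    caching: CachingConfig | None = None
    update_counts: list[np.ndarray] = field(default_factory=list)

    @property
    def final_accuracy(self) -> float:
        return self.accuracy_trace[-1][1] if self.accuracy_trace else float("nan")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of ``y = a * x**b`` on log-log axes."""

    exponent: float
    prefactor: float
    r_squared: float


def train_to_criterion(
    train: LabeledImageSet,
    valid: LabeledImageSet,
    n_hidden: int,
    config: TrainingConfig,
    strategy: StrategySpec | None = None,
    caching: CachingConfig | None = None,
    track_alphas: tuple[float, ...] = (),
    potentiation_only: bool = False,
    count_windows: tuple[tuple[int, int], ...] = (),
    log_path=None,
) -> TrainRecord:
    """Train a fresh network until the validation accuracy criterion is met.

    Per sample: forward -> backprop proposal -> restriction -> apply (directly
    or through the caching rule) -> charge the ledger.  Validation runs every
    ``config.eval_every`` presentations; training stops at the first
    evaluation meeting ``config.criterion_accuracy`` or after
    ``config.max_epochs`` epochs.  Divergence (non-finite outputs) flags the
    record instead of raising.

    ``count_windows`` are half-open intervals of sample indices; for each, the
    per-synapse count of nonzero applied input-layer updates is returned
    (used for the update-diversity index).
    """
    strategy = strategy or StrategySpec()
    rng = np.random.default_rng(config.seed)
    weights = init_weights(
        train.n_features,
        n_hidden,
        train.n_classes,
        init_sd=config.init_sd,
        rng=rng,
        beta=config.beta,
        activation_variant=config.activation_variant,
        output_variant=config.output_variant,
    )
    state = init_strategy(strategy, (weights.W_in.shape, weights.W_out.shape), rng)
    ledger = EnergyLedger(track_alphas=track_alphas, potentiation_only=potentiation_only)
    cache = CacheState(weights, caching) if caching is not None else None
    counts = [np.zeros(weights.W_in.shape, dtype=np.int64) for _ in count_windows]

    X_aug = np.concatenate([train.features, np.ones((train.n_samples, 1))], axis=1)
    targets = train.targets
    labels = train.labels
    lr = config.learning_rate
    needs_err = strategy.selection_metric == "neuron_error"
    needs_act = strategy.selection_metric == "neuron_activity"

    log_fh = open(log_path, "w") if log_path is not None else None
    accuracy_trace: list[tuple[int, float]] = []
    samples_seen = 0
    converged = diverged = False

    def evaluate() -> float:
        acc = evaluate_accuracy(weights, valid)
        accuracy_trace.append((samples_seen, acc))
        if log_fh is not None:
            import json

            row = {"samples_seen": samples_seen, "validation_accuracy": acc}
            row.update(ledger.totals())
            log_fh.write(json.dumps(row) + "\n")
        return acc

    try:
        for _epoch in range(config.max_epochs):
            order = rng.permutation(train.n_samples)
            for idx in order:
                x_aug = X_aug[idx]
                trace = forward(weights, None, x_aug=x_aug)
                if not np.isfinite(trace.y).all():
                    diverged = True
                    break
                proposal = backprop_proposal(weights, trace, None, targets[idx], lr, x_aug=x_aug)
                restricted = restrict_proposal(
                    state,
                    proposal,
                    sample_label=int(labels[idx]),
                    hidden_errors=(-proposal.dW_in[:, -1] / lr) if needs_err else None,
                    hidden_activities=trace.a_hidden if needs_act else None,
                )
                try:
                    if cache is not None:
                        caching_step(cache, restricted, ledger)
                        cache.write_effective(weights)
                    else:
                        apply_update(weights, restricted)
                        ledger.charge_update(restricted.dW_in, "in")
                        ledger.charge_update(restricted.dW_out, "out")
                except FloatingPointError:
                    diverged = True
                    break
                for w, (lo, hi) in enumerate(count_windows):
                    if lo <= samples_seen < hi:
                        counts[w] += restricted.dW_in != 0
                samples_seen += 1
                if samples_seen % config.eval_every == 0:
                    if evaluate() >= config.criterion_accuracy:
                        converged = True
                        break
            if converged or diverged:
                break
        if not accuracy_trace:
            evaluate()
    finally:
        if log_fh is not None:
            log_fh.close()

    return TrainRecord(
        T=samples_seen,
        converged=converged,
        diverged=diverged,
        ledger=ledger,
        accuracy_trace=accuracy_trace,
        weights=weights,
        config=config,
        strategy=strategy,
        caching=caching,
        update_counts=counts,
    )


def count_update_window(
    train: LabeledImageSet,
    weights: MLPWeights,
    config: TrainingConfig,
    strategy: StrategySpec,
    n_samples: int,
    seed: int,
    state: StrategyState | None = None,
) -> np.ndarray:
    """Continue training a copy of ``weights`` for ``n_samples`` presentations,
    returning per-synapse counts of nonzero applied input-layer updates.

    Used to probe update diversity in a window at an arbitrary point of
    training without disturbing the trained weights.
    """
    rng = np.random.default_rng(seed)
    w = weights.copy()
    if state is None:
        state = init_strategy(strategy, (w.W_in.shape, w.W_out.shape), rng)
    counts = np.zeros(w.W_in.shape, dtype=np.int64)
    X_aug = np.concatenate([train.features, np.ones((train.n_samples, 1))], axis=1)
    lr = config.learning_rate
    seen = 0
    while seen < n_samples:
        for idx in rng.permutation(train.n_samples):
            x_aug = X_aug[idx]
            trace = forward(w, None, x_aug=x_aug)
            proposal = backprop_proposal(w, trace, None, train.targets[idx], lr, x_aug=x_aug)
            restricted = restrict_proposal(state, proposal, sample_label=int(train.labels[idx]))
            apply_update(w, restricted)
            counts += restricted.dW_in != 0
            seen += 1
            if seen >= n_samples:
                break
    return counts


# ---------------------------------------------------------------------------
# Scaling analysis
# ---------------------------------------------------------------------------

def fit_power_law(xs, ys) -> PowerLawFit:
    """Least-squares fit of ``log y = log a + b log x``; exact on noiseless power laws."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.size < 2 or xs.size != ys.size:
        raise ValueError("need at least two (x, y) pairs")
    if (xs <= 0).any() or (ys <= 0).any():
        raise ValueError("power-law fitting needs strictly positive data")
    lx, ly = np.log(xs), np.log(ys)
    if np.ptp(lx) == 0:
        raise ValueError("all x values identical; slope is undefined")
    b, loga = np.polyfit(lx, ly, 1)
    resid = ly - (loga + b * lx)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PowerLawFit(exponent=float(b), prefactor=float(np.exp(loga)), r_squared=r2)


def extrapolate_ratio(
    exponent: float, n_syn_target: float, syn_per_hidden: float, N_h_ref: float
) -> float:
    """Fold-increase in energy when scaling from ``N_h_ref`` hidden units to a
    network with ``n_syn_target`` synapses (``n_syn_target / syn_per_hidden``
    equivalent hidden units), under a fitted power law with the given exponent."""
    if min(n_syn_target, syn_per_hidden, N_h_ref) <= 0:
        raise ValueError("sizes must be positive")
    n_h_eq = n_syn_target / syn_per_hidden
    return float((n_h_eq / N_h_ref) ** exponent)


def nearest_decade(x: float) -> float:
    """Nearest power of ten (10 ** round(log10 x))."""
    if x <= 0:
        raise ValueError("x must be positive")
    return float(10.0 ** round(np.log10(x)))


def round_one_significant(x: float) -> float:
    """Round to one significant figure."""
    if x == 0:
        return 0.0
    mag = np.floor(np.log10(abs(x)))
    return float(round(x / 10**mag) * 10**mag)


def update_probability_q(update_counts: np.ndarray, T: int | None = None) -> float:
    """Inverse Simpson index of per-synapse update probabilities.

    ``p_i = count_i / sum(counts)``; ``q = 1 / (N * sum p_i^2)`` where N is
    the number of synapses considered.  (``T`` is accepted for signature
    symmetry with run records but not needed: q is invariant to the
    normalization of the counts.)
    """
    counts = np.asarray(update_counts, dtype=np.float64).ravel()
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all counts are zero; q is undefined")
    p = counts / total
    return float(1.0 / (counts.size * (p**2).sum()))
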