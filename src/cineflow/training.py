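"""Case-level cross-validated training of the flow network.

Training samples are (frame window, ground-truth displacement, blood-pool
mask) triples, one per cardiac phase per case, with cyclic temporal windows.
Fold splitting is by *case*, never by image, so no subject contributes to
both the training and evaluation side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import window_indices
from .losses import epe_loss
from .network import FlowUNet, NetworkConfig, NetworkOutput, build_network
from .nn import Adam, Tensor, batchnorm_states, masked_epe, weighted_sum
from .phantom import Phantom
from .preprocess import displacement_to_velocity, normalize_intensities, velocity_to_displacement
from .types import (
    BloodPoolMask,
    CineSequence,
    DisplacementField,
    FlowField,
    ValidationError,
)


@dataclass(frozen=True)
class TrainConfig:
    folds: int = 5
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class FlowCase:
    """One training/evaluation case: normalized cine, target displacement, mask."""

    case_id: str
    cine: CineSequence
    gt: DisplacementField
    mask: BloodPoolMask

    def __post_init__(self) -> None:
        if self.gt.shape != self.cine.shape or self.mask.shape != self.cine.shape:
            raise ValidationError("case components have inconsistent shapes")


@dataclass
class CVResult:
    """Out-of-fold predictions and training histories of a cross-validation run."""

    displacements: Dict[str, DisplacementField]
    velocities: Dict[str, FlowField]
    fold_map: Dict[str, int]
    histories: List[List[float]]  # per fold, mean total loss per epoch
    models: List[FlowUNet]  # per-fold trained networks


def case_from_phantom(ph: Phantom, case_id: str, normalize: bool = True) -> FlowCase:
    """Package a phantom as a training case (normalized cine + displacement truth)."""
    cine = ph.cine
    if normalize:
        cine, _ = normalize_intensities(cine, ph.mask)
    gt = velocity_to_displacement(ph.truth, ph.cine.meta)
    return FlowCase(case_id=case_id, cine=cine, gt=gt, mask=ph.mask)


def split_folds(case_ids: Sequence[str], k: int, seed: int = 0) -> Dict[str, int]:
    """Deterministic case-level partition into ``k`` folds of near-equal size."""
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate case ids")
    if k > len(ids):
        raise ValidationError(f"cannot make {k} folds from {len(ids)} cases")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, k)
    fold_map: Dict[str, int] = {}
    for f, chunk in enumerate(chunks):
        for i in chunk:
            fold_map[ids[i]] = f
    return fold_map


def _build_samples(cases: Sequence[FlowCase], window: int):
    """Stack samples from all phases of all cases."""
    k = window // 2
    X, G, M = [], [], []
    for case in cases:
        T = case.cine.frames.shape[0]
        if window > T:
            raise ValidationError(f"window {window} exceeds {T} phases")
        for t in range(T):
            idx = window_indices(T, t, k)
            X.append(case.cine.frames[idx])
            G.append(np.stack([case.gt.dx[t], case.gt.dy[t]]))
            M.append(case.mask.labels[t] > 0)
    return np.asarray(X), np.asarray(G), np.asarray(M, dtype=bool)


def train_fold(
    train_cases: Sequence[FlowCase],
    val_cases: Sequence[FlowCase],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
) -> Tuple[FlowUNet, List[float]]:
    """Train one model on ``train_cases``, minimizing the deep-supervision loss.

    Returns the model and the per-epoch mean training loss history. The run
    is reproducible: fold seed controls weight init (through ``net_cfg``)
    and batch order.
    """
    if not train_cases:
        raise ValidationError("empty training set")
    net = build_network(net_cfg)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate)
    X, G, M = _build_samples(train_cases, net_cfg.window)
    n = X.shape[0]
    rng = np.random.default_rng(train_cfg.seed)
    weights = list(net_cfg.aux_weights) + [1.0]
    history: List[float] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            sel = order[start : start + train_cfg.batch_size]
            preds = net.forward(Tensor(X[sel]), training=True)
            terms = [masked_epe(p, G[sel], M[sel]) for p in preds]
            loss = weighted_sum(terms, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}; "
                    "check learning rate / input scaling"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    _recalibrate_batchnorm(net, X, train_cfg.batch_size)
    return net, history


def _recalibrate_batchnorm(net: FlowUNet, X: np.ndarray, batch_size: int) -> None:
    """Precise-BN pass: re-estimate inference statistics with the final
    weights so eval-mode predictions match the trained behaviour."""
    states = batchnorm_states(net)
    for st in states:
        st.start_collect()
    for start in range(0, X.shape[0], batch_size):
        net.forward(Tensor(X[start : start + batch_size]), training=True)
    for st in states:
        st.finalize_collect()


def predict_case(net: FlowUNet, case: FlowCase, batch_size: int = 8) -> DisplacementField:
    """Out-of-sample inference for every phase; predictions are zeroed outside
    the blood pool (the loss never constrains those pixels)."""
    window = net.cfg.window
    k = window // 2
    T, H, W = case.cine.shape
    stacks = np.stack([case.cine.frames[window_indices(T, t, k)] for t in range(T)])
    dx = np.zeros((T, H, W))
    dy = np.zeros((T, H, W))
    for start in range(0, T, batch_size):
        batch = stacks[start : start + batch_size]
        outs = net.forward(Tensor(batch), training=False)
        final = outs[3].data
        dx[start : start + batch.shape[0]] = final[:, 0]
        dy[start : start + batch.shape[0]] = final[:, 1]
    pool = case.mask.binary()
    return DisplacementField(dx=dx * pool, dy=dy * pool)


def mean_case_epe(pred: DisplacementField, case: FlowCase) -> float:
    """Masked displacement EPE averaged over all phases of one case."""
    T = pred.shape[0]
    vals = [
        epe_loss(
            np.stack([pred.dx[t], pred.dy[t]]),
            np.stack([case.gt.dx[t], case.gt.dy[t]]),
            case.mask.labels[t] > 0,
        )
        for t in range(T)
    ]
    return float(np.mean(vals))


def zero_baseline_epe(cases: Sequence[FlowCase]) -> float:
    """EPE of the all-zero displacement predictor (the natural null model)."""
    vals = []
    for case in cases:
        zero = DisplacementField(dx=np.zeros(case.gt.shape), dy=np.zeros(case.gt.shape))
        vals.append(mean_case_epe(zero, case))
    return float(np.mean(vals))


def cross_validate(
    cases: Sequence[FlowCase],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
) -> CVResult:
    """K-fold cross-validation at case level.

    Each case is predicted exactly once, by the model of the fold that
    excluded it; final displacements are also converted to velocities for
    downstream evaluation.
    """
    ids = [c.case_id for c in cases]
    fold_map = split_folds(ids, train_cfg.folds, seed=train_cfg.seed)
    by_id = {c.case_id: c for c in cases}
    displacements: Dict[str, DisplacementField] = {}
    velocities: Dict[str, FlowField] = {}
    histories: List[List[float]] = []
    models: List[FlowUNet] = []
    for f in range(train_cfg.folds):
        train_set = [by_id[i] for i in ids if fold_map[i] != f]
        val_set = [by_id[i] for i in ids if fold_map[i] == f]
        net, history = train_fold(train_set, val_set, net_cfg, train_cfg)
        histories.append(history)
        models.append(net)
        for case in val_set:
            assert fold_map[case.case_id] == f  # leakage guard
            pred = predict_case(net, case)
            displacements[case.case_id] = pred
            velocities[case.case_id] = displacement_to_velocity(pred, case.cine.meta)
    missing = set(ids) - set(displacements)
    if missing:
        raise RuntimeError(f"cases never predicted: {missing}")
    return CVResult(
        displacements=displacements,
        velocities=velocities,
        fold_map=fold_map,
        histories=histories,
        models=models,
    )
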