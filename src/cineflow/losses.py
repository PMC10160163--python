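"""Masked end-point-error loss and the deeply supervised total loss.

EPE between two displacement fields is the Euclidean distance of the vector
difference averaged over the ``M`` blood-pool pixels:

``EPE = (1/M) * sum_i sqrt((dx_p - dx_g)^2 + (dy_p - dy_g)^2)``

The total training loss adds the weighted EPEs of the three auxiliary heads
to the final head's EPE, all against the same ground truth and mask:

``Loss = EPE(G, O) + sum_c w_c * EPE(G, P_c)``
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .network import NetworkConfig, NetworkOutput
from .types import DegenerateInputError, ValidationError


def _as_slice(field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValidationError(f"expected [2,H,W] displacement slice, got {field.shape}")
    return field


def epe_loss(pred: np.ndarray, gt: np.ndarray, mask: np.ndarray) -> float:
    """Mean end-point error (pixels) over masked pixels of one phase.

    ``pred``/``gt`` are ``[2, H, W]`` (x then y displacement); ``mask`` is a
    boolean or 0/1 array ``[H, W]``.
    """
    pred = _as_slice(pred)
    gt = _as_slice(gt)
    m = np.asarray(mask).astype(bool)
    if m.shape != pred.shape[1:]:
        raise ValidationError(f"mask shape {m.shape} != field shape {pred.shape[1:]}")
    if not m.any():
        raise DegenerateInputError("empty mask: EPE undefined")
    diff = pred - gt
    err = np.hypot(diff[0], diff[1])
    return float(err[m].mean())


def total_loss(
    out: NetworkOutput,
    gt: np.ndarray,
    mask: np.ndarray,
    cfg: NetworkConfig,
) -> float:
    """Deep-supervision loss: final-head EPE plus weighted auxiliary EPEs."""
    if len(out.predictions) != 4:
        raise ValidationError(f"expected 4 predictions, got {len(out.predictions)}")
    loss = epe_loss(out.final, gt, mask)
    for w, aux in zip(cfg.aux_weights, out.predictions[:3]):
        loss += w * epe_loss(aux, gt, mask)
    return float(loss)
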