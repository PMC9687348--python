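"""Backpropagation-based pixel relevance for the trained network.

Two attribution routes are provided.  ``grad_x_input`` multiplies the
gradient of a scalar readout of the predicted signal by the input itself and
sums over colour channels — the standard sensitivity-times-signal map.
``eps_lrp`` is epsilon-rule layer-wise relevance propagation; it is exact
for plain chains of linear/convolutional layers with ReLU, and those are the
only layers it propagates through.  The full network contains attention
blocks, for which epsilon-LRP is not well defined; requesting ``eps_lrp`` on
it falls back to ``grad_x_input`` with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from . import nn
from .model import AxisProjectionNet
from .preprocess import WindowedSample

__all__ = ["RelevanceMap", "relevance_map", "lrp_sequential", "roi_concentration"]

logger = logging.getLogger(__name__)

ROI_RATIO_CAP = 1e9


@dataclass(frozen=True)
class RelevanceMap:
    values: np.ndarray          # (T, H, W), signed
    input_ref: str = ""

    def normalized(self) -> np.ndarray:
        peak = np.abs(self.values).max()
        return self.values / peak if peak > 0 else self.values.copy()


def _grad_x_input(model: AxisProjectionNet, video: np.ndarray,
                  output_reduction) -> np.ndarray:
    x = Tensor(video[None], requires_grad=True)   # (1, 3, T, H, W)
    out = model(x)                                # (1, T)
    target = output_reduction(out)
    target.backward()
    rel = (x.grad[0] * video).sum(axis=0)         # sum over channels -> (T, H, W)
    return rel


def relevance_map(model: AxisProjectionNet, sample: WindowedSample | np.ndarray,
                  method: str = "grad_x_input", output_reduction=None,
                  input_ref: str = "") -> RelevanceMap:
    """Per-pixel relevance of the input window for the predicted signal.

    The scalar attribution target is a reduction of the length-T output
    (default: its sum).  The raw signed map is returned; use
    :meth:`RelevanceMap.normalized` for visualisation copies.
    """
    video = sample.video if isinstance(sample, WindowedSample) else np.asarray(sample)
    if video.ndim != 4 or video.shape[0] != 3:
        raise ValueError("sample video must be (3, T, H, W)")
    if output_reduction is None:
        output_reduction = lambda out: out.sum()
    was_training = model.training
    model.eval()
    try:
        if method == "eps_lrp":
            warnings.warn("eps_lrp is not defined through attention blocks; "
                          "falling back to grad_x_input")
            method = "grad_x_input"
        if method != "grad_x_input":
            raise ValueError(f"unknown attribution method: {method}")
        rel = _grad_x_input(model, video, output_reduction)
    finally:
        model.train(was_training)
    return RelevanceMap(values=rel, input_ref=input_ref)


def lrp_sequential(layers: list, x: np.ndarray, eps: float = 1e-9,
                   return_layerwise: bool = False):
    """Epsilon-rule LRP through a chain of Linear / Conv / ReLU modules.

    Relevance starts as the output activations and is redistributed backwards
    with the epsilon rule ``R_i = x_i * sum_j w_ij R_j / (z_j + eps*sign z_j)``;
    ReLU layers pass relevance through their active units unchanged.  For a
    bias-free chain the rule conserves total relevance layer by layer (up to
    the epsilon stabiliser).
    """
    activations = [np.asarray(x, dtype=float)]
    for layer in layers:
        t = Tensor(activations[-1])
        activations.append(layer(t).numpy())
    relevance = activations[-1].copy()
    layerwise = [relevance.sum()]
    for layer, a_in in zip(reversed(layers), reversed(activations[:-1])):
        if isinstance(layer, nn.ReLU):
            pass  # relevance of inactive units is already zero
        elif isinstance(layer, (nn.Linear, nn.Conv2d, nn.Conv1d)):
            t_in = Tensor(a_in, requires_grad=True)
            z = layer(t_in)
            stab = z.numpy() + eps * np.where(z.numpy() >= 0, 1.0, -1.0)
            z.backward(relevance / stab)
            relevance = a_in * t_in.grad
        else:
            raise TypeError(f"eps-LRP rule not defined for {type(layer).__name__}")
        layerwise.append(relevance.sum())
    result = RelevanceMap(values=relevance)
    if return_layerwise:
        return result, layerwise
    return result


def roi_concentration(rel: RelevanceMap | np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean |relevance| inside the mask over mean |relevance| outside.

    Time-averaged; a map that is zero outside the mask returns the capped
    sentinel ``ROI_RATIO_CAP`` rather than infinity.
    """
    values = rel.values if isinstance(rel, RelevanceMap) else np.asarray(rel)
    mask = np.asarray(roi_mask, dtype=bool)
    if values.shape[-2:] != mask.shape:
        raise ValueError("mask shape must match the map's spatial shape")
    if not mask.any():
        raise ValueError("empty ROI mask")
    if mask.all():
        raise ValueError("mask covers the whole frame; no outside region")
    mag = np.abs(values).mean(axis=0)   # time average -> (H, W)
    inside = mag[mask].mean()
    outside = mag[~mask].mean()
    if outside == 0:
        return ROI_RATIO_CAP if inside > 0 else 1.0
    return float(inside / outside)
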