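"""Layer-adaptive magnitude-based pruning (LAMP) scores and global masks.

The LAMP score of weight ``u`` in a layer whose flattened weights are
sorted ascending by magnitude is

    score(u; W) = W[u]^2 / sum_{v >= u} W[v]^2

i.e. its squared magnitude relative to the tail sum over all weights at
least as large.  The score is invariant to rescaling a layer, strictly
increasing in |W| within a layer, and the largest-magnitude weight of every
layer scores exactly 1 — so pruning globally by ascending score can never
empty a layer (no layer collapse), while per-layer sparsities emerge
automatically from a single global target.
"""

from __future__ import annotations

import math

import numpy as np

WeightTensorSet = dict[str, np.ndarray]
PruneMask = dict[str, np.ndarray]


def lamp_scores(layer: np.ndarray) -> np.ndarray:
    """Per-weight LAMP scores, same shape as the input tensor.

    Magnitude ties are broken by original flat index (stable sort), giving a
    total order and reproducible scores.  Raises on an all-zero layer, for
    which the score's denominator is undefined.
    """
    arr = np.asarray(layer, dtype=float)
    if arr.size == 0:
        raise ValueError("empty layer")
    flat = arr.reshape(-1)
    if not np.any(flat):
        raise ValueError("all-zero layer: LAMP score undefined")
    order = np.argsort(np.abs(flat), kind="stable")
    # normalize by the largest magnitude before squaring: the score is a
    # ratio, so this is exact in real arithmetic and avoids underflow of
    # tiny weights' squares in float64
    scaled = flat[order] / np.abs(flat[order[-1]])
    sq = scaled**2
    tail = np.cumsum(sq[::-1])[::-1]  # tail[u] = sum_{v>=u} sq[v]
    scores_sorted = sq / tail
    scores = np.empty_like(flat)
    scores[order] = scores_sorted
    return scores.reshape(arr.shape)


def global_prune_mask(tensors: WeightTensorSet, target_sparsity: float) -> PruneMask:
    """Boolean keep-masks removing the globally lowest-scored weights.

    Removes ``ceil(target_sparsity * N)`` weights in ascending score order,
    skipping each layer's maximum-score weight so every layer retains at
    least one connection.  Achieved sparsity therefore lands in
    ``[target, target + 1/N]``.
    """
    if not tensors:
        raise ValueError("empty tensor set")
    if not 0.0 <= target_sparsity < 1.0:
        raise ValueError(f"target_sparsity must lie in [0, 1), got {target_sparsity}")

    entries: list[tuple[float, int, int]] = []  # (score, layer_index, flat_index)
    names = list(tensors)
    protected: dict[str, int] = {}
    total = 0
    for li, name in enumerate(names):
        scores = lamp_scores(tensors[name]).reshape(-1)
        total += scores.size
        # the stable-sorted maximum: last index in the magnitude order
        protected[name] = int(
            np.argsort(np.abs(np.asarray(tensors[name], float).reshape(-1)), kind="stable")[-1]
        )
        for fi, s in enumerate(scores):
            if fi != protected[name]:
                entries.append((float(s), li, fi))

    n_remove = math.ceil(target_sparsity * total - 1e-12)
    if n_remove > len(entries):
        raise ValueError(
            f"target sparsity {target_sparsity} would leave some layer empty "
            f"({n_remove} removals requested, {len(entries)} prunable weights)"
        )
    entries.sort()
    mask: PruneMask = {
        name: np.ones(np.asarray(t).size, dtype=bool) for name, t in tensors.items()
    }
    for _score, li, fi in entries[:n_remove]:
        mask[names[li]][fi] = False
    return {name: m.reshape(np.asarray(tensors[name]).shape) for name, m in mask.items()}


def achieved_sparsity(mask: PruneMask) -> float:
    total = sum(m.size for m in mask.values())
    kept = sum(int(m.sum()) for m in mask.values())
    return 1.0 - kept / total


def channel_prune_mask(tensors: WeightTensorSet, target_sparsity: float) -> PruneMask:
    """Structured variant: prune whole output channels (axis 0 groups).

    A channel's score is the sum of its elements' LAMP scores; channels are
    removed globally in ascending score order until the removed weight
    fraction reaches the target, keeping at least one channel per layer.
    """
    if not tensors:
        raise ValueError("empty tensor set")
    if not 0.0 <= target_sparsity < 1.0:
        raise ValueError(f"target_sparsity must lie in [0, 1), got {target_sparsity}")
    entries: list[tuple[float, int, int, int]] = []  # (score, layer, channel, weights)
    names = list(tensors)
    total = 0
    for li, name in enumerate(names):
        arr = np.asarray(tensors[name], dtype=float)
        total += arr.size
        ch_scores = lamp_scores(arr).reshape(arr.shape[0], -1).sum(axis=1)
        best = int(np.argmax(ch_scores))
        per_ch = arr.size // arr.shape[0]
        for ci, s in enumerate(ch_scores):
            if ci != best:
                entries.append((float(s), li, ci, per_ch))
    entries.sort()
    mask: PruneMask = {
        name: np.ones(np.asarray(t).shape, dtype=bool) for name, t in tensors.items()
    }
    removed = 0
    for score, li, ci, per_ch in entries:
        if removed / total >= target_sparsity:
            break
        mask[names[li]][ci] = False
        removed += per_ch
    return mask


def sparsity_from_speedup(speedup: float) -> float:
    """Config alias: a target compute speedup ratio s maps to sparsity 1 − 1/s."""
    if speedup < 1.0:
        raise ValueError("speedup ratio must be >= 1")
    return 1.0 - 1.0 / speedup
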