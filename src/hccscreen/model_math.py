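"""Reference forward functions of the segmentation and fusion model family.

Pure numpy implementations, at toy scale, of the training objectives and
attention blocks used by the underlying detection/classification networks:

* the supervised segmentation loss (cross-entropy plus a soft-IoU penalty),
* the confidence-gated consistency loss between a weakly perturbed
  prediction and its feature-/strongly-perturbed counterparts,
* the self-/cross-/cross-self attention matrix products, and
* the weighted fusion of expert outputs.

No training, gradients or learned weights: inputs are explicit arrays, which
makes every function checkable by hand arithmetic. The attention products
are implemented literally as the bare matrix forms (no softmax, no 1/sqrt(d)
scaling); a conventional scaled-softmax mode is available as an option.

Array convention: prediction/ground-truth maps are ``(C, *spatial)`` with
class entries in [0, 1]; token matrices are ``(tokens, features)``.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def _check_pair(Y: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    if Y.shape != P.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {P.shape}")
    if Y.ndim < 1:
        raise ValueError("maps must have a leading class axis")
    for name, a in (("Y", Y), ("P", P)):
        if np.any((a < 0) | (a > 1)):
            raise ValueError(f"{name} entries must lie in [0, 1]")
    return Y, P


def _reduce(per_position: np.ndarray, reduction: str) -> float:
    if reduction == "mean":
        return float(np.mean(per_position))
    if reduction == "sum":
        return float(np.sum(per_position))
    raise ValueError(f"unknown reduction {reduction!r}")


def supervised_seg_loss(
    Y: np.ndarray, P: np.ndarray, eps: float = EPS, reduction: str = "mean"
) -> float:
    """Cross-entropy plus soft-IoU segmentation loss.

    Per spatial position: ``-sum_i Y_i log P_i`` plus
    ``1 - (1/C) sum_i  Y_i P_i / (Y_i + P_i - Y_i P_i)``, summed over the C
    classes and averaged (default) over positions. The IoU ratio is
    epsilon-stabilised so that an all-zero class contributes a perfect ratio
    of 1 rather than 0/0.
    """
    Y, P = _check_pair(Y, P)
    ce = -np.sum(Y * np.log(P + eps), axis=0)
    ratio = (Y * P + eps) / (Y + P - Y * P + eps)
    C = Y.shape[0]
    iou = 1.0 - ratio.sum(axis=0) / C
    return _reduce(ce + iou, reduction)


def consistency_loss(
    P_w: np.ndarray,
    P_fp: np.ndarray,
    P_s1: np.ndarray,
    P_s2: np.ndarray,
    tau: float = 0.95,
    eps: float = EPS,
    reduction: str = "mean",
) -> float:
    """Confidence-gated consistency loss among perturbed predictions.

    At each spatial position where the maximum class confidence of the
    weak-view prediction ``P_w`` reaches ``tau``, the cross-entropies of the
    feature-perturbed and two strong-view predictions against ``P_w`` are
    summed; positions below the threshold contribute nothing.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    P_w, P_fp = _check_pair(P_w, P_fp)
    _, P_s1 = _check_pair(P_w, P_s1)
    _, P_s2 = _check_pair(P_w, P_s2)
    gate = np.max(P_w, axis=0) >= tau

    def ce(pred: np.ndarray) -> np.ndarray:
        return -np.sum(P_w * np.log(pred + eps), axis=0)

    per_pos = gate * (ce(P_fp) + ce(P_s1) + ce(P_s2))
    return _reduce(per_pos, reduction)


def _check_tokens(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be a (tokens, features) matrix")
    return x


def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def self_attention(
    x: np.ndarray,
    W_Q: np.ndarray,
    W_K: np.ndarray,
    W_V: np.ndarray,
    conventional: bool = False,
) -> np.ndarray:
    """Self-attention as the bare product (x W_Q)(x W_K)^T (x W_V).

    ``conventional=True`` applies row-softmax of the scaled similarity
    instead, matching the standard transformer formulation.
    """
    return cross_attention(x, x, W_Q, W_K, W_V, conventional=conventional)


def cross_attention(
    x_src: np.ndarray,
    x_tgt: np.ndarray,
    W_Q: np.ndarray,
    W_K: np.ndarray,
    W_V: np.ndarray,
    conventional: bool = False,
) -> np.ndarray:
    """Cross-attention (x_src W_Q)(x_tgt W_K)^T (x_tgt W_V)."""
    x_src = _check_tokens(x_src, "x_src")
    x_tgt = _check_tokens(x_tgt, "x_tgt")
    q = x_src @ np.asarray(W_Q, dtype=float)
    k = x_tgt @ np.asarray(W_K, dtype=float)
    v = x_tgt @ np.asarray(W_V, dtype=float)
    sim = q @ k.T
    if conventional:
        sim = _softmax(sim / np.sqrt(q.shape[1]))
    return sim @ v


def cross_self_attention(
    x_src: np.ndarray,
    x_tgt: np.ndarray,
    W_Q: np.ndarray,
    W_K: np.ndarray,
    W_V: np.ndarray,
    conventional: bool = False,
) -> np.ndarray:
    """Composition SA(SA(x_src) + CA(x_src, x_tgt)) with shared projections."""
    sa = self_attention(x_src, W_Q, W_K, W_V, conventional=conventional)
    ca = cross_attention(x_src, x_tgt, W_Q, W_K, W_V, conventional=conventional)
    return self_attention(sa + ca, W_Q, W_K, W_V, conventional=conventional)


def weighted_fusion(
    expert_outputs, gamma, normalize: bool = False
) -> np.ndarray:
    """Weighted sum of expert prediction vectors.

    ``expert_outputs`` is an (experts, outputs) array (or list of vectors);
    ``gamma`` one weight per expert. ``normalize=True`` divides the weights
    by their sum.
    """
    outputs = np.asarray(expert_outputs, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if outputs.ndim != 2 or g.ndim != 1 or outputs.shape[0] != g.size:
        raise ValueError(
            f"need (experts, outputs) and matching gamma; got {outputs.shape} "
            f"and {g.shape}"
        )
    if normalize:
        s = g.sum()
        if s == 0:
            raise ValueError("cannot normalize zero-sum weights")
        g = g / s
    return g @ outputs
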