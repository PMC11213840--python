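"""Synthetic intermediate projections (SIPs) from sparse acquisitions.

A 120-view acquisition is down-sampled to 30 views by keeping every fourth
projection starting with the first (1-based indices 1, 5, 9, ..., 117).
The three missing views in each gap — angular offsets 1, 2 and 3 — are
synthesised by three separately trained networks, each mapping the full
30-view stack to the 30 projections at its offset.  The 30 acquired views
interleaved with the 90 synthetic ones form a full 120-view set again.

A training-free baseline — angle-linear interpolation between the two
acquired neighbours, with weights ((4-offset)/4, offset/4) and the last gap
wrapping around 360 deg — is provided both as a comparison method and as
the base prediction the network refines: the net outputs a residual added
to the interpolated view, so an untrained net already produces sensible
projections and training concentrates on the (mostly noise-driven)
discrepancy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._nn import F32, Adam, UNet
from .projector import ProjectionSet

OFFSETS = (1, 2, 3)


def downsample_projections(
    p: ProjectionSet, factor: int = 4, start_index: int = 1
) -> ProjectionSet:
    """Keep every ``factor``-th projection starting at 1-based ``start_index``."""
    n = p.n_projections
    if n % factor != 0:
        raise ValueError(
            f"down-sampling factor {factor} does not divide {n} projections"
        )
    keep = np.arange(start_index - 1, n, factor)
    return ProjectionSet(
        counts=p.counts[keep].copy(),
        angles_deg=p.angles_deg[keep].copy(),
        provenance=["acquired"] * len(keep),
        frame_duration_s=p.frame_duration_s,
        time_point_h=p.time_point_h,
    )


def _as_stack(sparse) -> np.ndarray:
    return sparse.counts if isinstance(sparse, ProjectionSet) else np.asarray(sparse, float)


def interpolate_sips(sparse, offset: int) -> np.ndarray:
    """Angle-linear blend of acquired neighbours at the given offset.

    The synthetic view between acquired neighbours k and k+1 at offset o is
    ``((4-o)/4) * view_k + (o/4) * view_{k+1}``; the last gap wraps to the
    first view (360 deg periodicity).
    """
    if offset not in OFFSETS:
        raise ValueError(f"offset must be one of {OFFSETS}, got {offset}")
    stack = _as_stack(sparse)
    if isinstance(sparse, ProjectionSet):
        steps = np.diff(sparse.angles_deg)
        if not np.allclose(steps, steps[0]):
            raise ValueError("sparse set must have uniform angular spacing")
    w1 = offset / 4.0
    return (1.0 - w1) * stack + w1 * np.roll(stack, -1, axis=0)


@dataclass
class SIPModel:
    """Three per-offset networks plus the training provenance."""

    offset_models: dict[int, UNet]
    loss_tag: str
    epochs: int
    seed: int
    loss_history: dict[int, list[float]] = field(default_factory=dict)


def _normalise(stack: np.ndarray) -> tuple[np.ndarray, float]:
    s = float(stack.max())
    if s <= 0:
        s = 1.0
    return (stack / s).astype(F32), s


def train_sip_model(
    training_pairs: list[tuple[np.ndarray, np.ndarray]],
    offset: int,
    loss_tag: str = "L2",
    epochs: int = 300,
    seed: int = 0,
    base_channels: int = 8,
    lr: float = 1e-3,
    batch_size: int = 4,
) -> tuple[UNet, list[float]]:
    """Train the network for one angular offset.

    Each pair is (sparse 30-view stack, target 30-view stack at the offset),
    arrays of identical shape.  Stacks are normalised by the sparse stack's
    maximum before the network and the target shares the same scale, so one
    model serves all count levels.  Returns the trained network and the
    per-epoch mean training loss.
    """
    if loss_tag not in ("L1", "L2"):
        raise ValueError(f"loss_tag must be 'L1' or 'L2', got {loss_tag!r}")
    if offset not in OFFSETS:
        raise ValueError(f"offset must be one of {OFFSETS}, got {offset}")
    if len(training_pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    shape = np.asarray(training_pairs[0][0]).shape
    for x, y in training_pairs:
        if np.asarray(x).shape != shape or np.asarray(y).shape != shape:
            raise ValueError("all training pairs must share one matrix size")
    if shape[1] % 4 or shape[2] % 4:
        raise ValueError("projection height/width must be divisible by 4")

    rng = np.random.default_rng(seed)
    net = UNet(channels=shape[0], base=base_channels, seed=seed)
    opt = Adam(net.layers, lr=lr)

    # pre-normalised tensors and residual targets (target - interpolation)
    xs, resid = [], []
    for x, y in training_pairs:
        xn, s = _normalise(np.asarray(x, float))
        yn = (np.asarray(y, float) / s).astype(F32)
        xs.append(xn)
        resid.append(yn - interpolate_sips(xn, offset).astype(F32))
    xs = np.stack(xs)
    resid = np.stack(resid)

    history: list[float] = []
    n = len(xs)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, batch_size):
            idx = order[b0 : b0 + batch_size]
            xb, rb = xs[idx], resid[idx]
            out = net.forward(xb, train=True)
            diff = out - rb
            if loss_tag == "L2":
                losses.append(float(np.mean(diff**2)))
                grad = (2.0 / diff.size) * diff
            else:
                losses.append(float(np.mean(np.abs(diff))))
                grad = np.sign(diff) / diff.size
            net.backward(grad.astype(F32))
            opt.step()
        history.append(float(np.mean(losses)))
    return net, history


def train_sip_models(
    pairs_by_offset: dict[int, list[tuple[np.ndarray, np.ndarray]]],
    loss_tag: str = "L2",
    epochs: int = 300,
    seed: int = 0,
    **kw,
) -> SIPModel:
    """Train all three offset networks and bundle them into a SIPModel."""
    models, hist = {}, {}
    for o in OFFSETS:
        models[o], hist[o] = train_sip_model(
            pairs_by_offset[o], o, loss_tag=loss_tag, epochs=epochs, seed=seed + o, **kw
        )
    return SIPModel(models, loss_tag=loss_tag, epochs=epochs, seed=seed, loss_history=hist)


def apply_offset_model(net: UNet, sparse_stack: np.ndarray, offset: int) -> np.ndarray:
    """One offset's synthetic projections for a sparse stack (clamped >= 0)."""
    xn, s = _normalise(np.asarray(sparse_stack, float))
    base = interpolate_sips(xn, offset)
    resid = net.forward(xn[None])[0].astype(float)
    return np.maximum((base + resid) * s, 0.0)


def generate_sips(model: SIPModel, sparse: ProjectionSet) -> np.ndarray:
    """All 3 x n_sparse synthetic projections, grouped by offset.

    Row layout: offset-1 views for gaps 0..n-1, then offset-2, then offset-3.
    """
    stack = _as_stack(sparse)
    out = []
    for o in OFFSETS:
        if o not in model.offset_models or model.offset_models[o] is None:
            raise ValueError(f"SIP model has no trained network for offset {o}")
        out.append(apply_offset_model(model.offset_models[o], stack, o))
    return np.concatenate(out, axis=0)


def interpolation_sips(sparse: ProjectionSet) -> np.ndarray:
    """Training-free counterpart of :func:`generate_sips` (same layout)."""
    stack = _as_stack(sparse)
    return np.concatenate([interpolate_sips(stack, o) for o in OFFSETS], axis=0)


def assemble_cusip_set(sparse: ProjectionSet, sips: np.ndarray) -> ProjectionSet:
    """Interleave acquired and synthetic views into a full set.

    With n acquired views at global 1-based indices 1, 5, ..., the offset-o
    synthetic view of gap k lands at global index 4k + 1 + o.  Provenance
    flags mark exactly the acquired views.
    """
    n = sparse.n_projections
    sips = np.asarray(sips, dtype=float)
    if sips.shape[0] != 3 * n:
        raise ValueError(
            f"expected {3 * n} synthetic projections for {n} acquired, got {sips.shape[0]}"
        )
    if sips.shape[1:] != sparse.counts.shape[1:]:
        raise ValueError("synthetic and acquired matrix sizes differ")
    steps = np.diff(sparse.angles_deg)
    if not np.allclose(steps, steps[0]):
        raise ValueError("sparse set must have uniform angular spacing")
    step = steps[0] / 4.0
    counts = np.empty((4 * n,) + sparse.counts.shape[1:], dtype=float)
    prov = ["synthetic"] * (4 * n)
    counts[0::4] = sparse.counts
    for o in OFFSETS:
        counts[o::4] = sips[(o - 1) * n : o * n]
    for k in range(0, 4 * n, 4):
        prov[k] = "acquired"
    angles = sparse.angles_deg[0] + step * np.arange(4 * n)
    return ProjectionSet(
        counts=np.maximum(counts, 0.0),
        angles_deg=angles,
        provenance=prov,
        frame_duration_s=sparse.frame_duration_s,
        time_point_h=sparse.time_point_h,
    )


def training_pairs_from_full_set(p: ProjectionSet) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Split one full acquisition into (sparse input, per-offset target) pairs."""
    sparse = downsample_projections(p)
    out = {}
    for o in OFFSETS:
        out[o] = (sparse.counts.copy(), p.counts[o::4].copy())
    return out
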