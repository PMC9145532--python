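"""Statistical positional-atlas construction from canonicalized worms.

The atlas entry for each neuron is the componentwise median of its canonical
positions over contributing worms (robust to outliers and resistant to
shrinkage, unlike the mean), with per-axis median absolute deviation as the
positional-variability statistic.  High-resolution head/tail sub-atlases can
be merged in by a closed-form rigid (Kabsch) alignment on shared neurons.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .io import Atlas, NeuronPointCloud, ValidationError


def build_atlas(clouds: Sequence[NeuronPointCloud], min_count: int = 1) -> Atlas:
    """Combine canonical labeled clouds into a median-position atlas.

    Every neuron name seen in at least ``min_count`` clouds gets an entry:
    componentwise median position, per-axis median absolute deviation, the
    contributing-worm count, and the (consistent) color index if present.
    """
    clouds = list(clouds)
    if not clouds:
        raise ValidationError("build_atlas requires at least one cloud")
    per_name: dict[str, list[np.ndarray]] = defaultdict(list)
    per_color: dict[str, set[int]] = defaultdict(set)
    order: list[str] = []
    for cloud in clouds:
        if cloud.names is None:
            raise ValidationError("atlas construction needs labeled clouds")
        for i, name in enumerate(cloud.names):
            if name not in per_name:
                order.append(name)
            per_name[name].append(cloud.positions[i])
            if cloud.colors is not None:
                per_color[name].add(int(cloud.colors[i]))
    for name, cols in per_color.items():
        if len(cols) > 1:
            raise ValidationError(f"conflicting color indices for {name}: {sorted(cols)}")
    names, pos, spread, counts, colors = [], [], [], [], []
    order = sorted(order)
    any_color = bool(per_color)
    for name in order:
        stack = np.array(per_name[name])
        if len(stack) < min_count:
            continue
        med = np.median(stack, axis=0)
        names.append(name)
        pos.append(med)
        spread.append(np.median(np.abs(stack - med), axis=0))
        counts.append(len(stack))
        if any_color:
            colors.append(per_color[name].pop() if per_color[name] else 0)
    if not names:
        raise ValidationError("no neuron met the minimum worm count")
    return Atlas(
        names, np.array(pos), spreads=np.array(spread),
        colors=np.array(colors) if any_color else None,
        counts=np.array(counts),
    )


def rigid_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping src → dst, no scaling.

    Closed-form Kabsch solution via SVD with a reflection guard
    (det(R) = +1 enforced).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 3:
        raise ValidationError("rigid fit needs at least 3 point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave the rotation about the common axis free
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise ValidationError("shared points are (near-)collinear; rigid fit is degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return R, t


def merge_subatlas(whole: Atlas, sub: Atlas, region: Iterable[str]) -> Atlas:
    """Replace a region of ``whole`` by a rigidly-aligned high-res sub-atlas.

    The rigid transform is fitted on neurons shared between ``sub`` and
    ``whole`` within ``region``; region entries of ``whole`` found in ``sub``
    are replaced by the transformed sub positions, everything else is left
    untouched (bitwise).
    """
    region = set(region)
    shared = [n for n in sub.names if n in region and n in set(whole.names)]
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared neurons in the region to align, got {len(shared)}"
        )
    sub_idx = {n: i for i, n in enumerate(sub.names)}
    whole_idx = {n: i for i, n in enumerate(whole.names)}
    src = sub.positions[[sub_idx[n] for n in shared]]
    dst = whole.positions[[whole_idx[n] for n in shared]]
    R, t = rigid_fit(src, dst)
    new_pos = whole.positions.copy()
    for n in sub.names:
        if n in region and n in whole_idx:
            new_pos[whole_idx[n]] = R @ sub.positions[sub_idx[n]] + t
    return Atlas(
        list(whole.names), new_pos,
        spreads=None if whole.spreads is None else whole.spreads.copy(),
        colors=None if whole.colors is None else whole.colors.copy(),
        counts=None if whole.counts is None else whole.counts.copy(),
    )


class AtlasBuilder(BaseEstimator):
    """Median-position atlas builder with a scikit-learn-style interface.

    ``fit`` consumes a list of canonical labeled clouds and exposes the
    resulting :class:`~wormalign.io.Atlas` as ``atlas_``.
    """

    def __init__(self, min_count: int = 1):
        self.min_count = min_count

    def fit(self, X: Sequence[NeuronPointCloud], y=None) -> "AtlasBuilder":
        self.atlas_ = build_atlas(X, min_count=self.min_count)
        return self
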