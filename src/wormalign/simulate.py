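"""Simulated perturbations and synthetic worm fixtures.

These generators reproduce the benchmark conditions used to validate the
aligner: a shared rigid jitter (one uniform ±5 μm vector per cloud),
axis cropping, random neuron dropout, smooth "biological noise" from a
random Gaussian-mixture deformation field (defaults: N = 100 centers,
displacement amplitude 6.1 μm), and randomized color assignments shared by
neuron identity across clouds.  ``synth_worm`` builds a bent-tube worm
silhouette plus a neuron cloud with known ground-truth canonical positions,
so the whole pipeline is testable without any external data.

All generators are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import DeformationParams, deformation_apply
from .io import CANONICAL, HullMask, NeuronPointCloud, ValidationError, neuron_name_list


@dataclass
class BioNoiseSpec:
    """Parameters of the simulated biological deformation field."""

    n_centers: int = 100
    amplitude: float = 6.1  # μm, fixed |d_n|
    sigma: float = 15.0  # μm influence radius
    seed: int = 0
    gaussian_magnitude: bool = False  # draw d_n ~ N(0, σ²I) instead of fixed |d_n|

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("amplitude must be non-negative")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


def rigid_jitter(
    cloud: NeuronPointCloud, max_shift: float = 5.0, seed: int = 0
) -> tuple[NeuronPointCloud, np.ndarray]:
    """Shift the whole cloud by one uniform vector in [−max_shift, max_shift]³."""
    if max_shift < 0:
        raise ValidationError("max_shift must be non-negative")
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-max_shift, max_shift, size=3)
    return cloud.with_positions(cloud.positions + shift), shift


def crop_cloud(
    cloud: NeuronPointCloud, axis: str, lo: float = -np.inf, hi: float = np.inf
) -> NeuronPointCloud:
    """Keep records whose ``axis`` coordinate lies in [lo, hi], order preserved."""
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    if lo >= hi:
        raise ValidationError("crop bounds must satisfy lo < hi")
    coord = cloud.positions[:, ax]
    keep = np.nonzero((coord >= lo) & (coord <= hi))[0]
    if len(keep) == 0:
        import warnings

        warnings.warn("crop removed every neuron")
    return cloud.subset(keep)


def dropout(
    cloud: NeuronPointCloud, n_remove: int, seed: int = 0
) -> tuple[NeuronPointCloud, list[str]]:
    """Remove ``n_remove`` uniformly chosen neurons (detection failure)."""
    n = len(cloud)
    if not 0 <= n_remove <= n:
        raise ValidationError(f"n_remove must be in [0, {n}]")
    rng = np.random.default_rng(seed)
    removed = np.sort(rng.choice(n, size=n_remove, replace=False))
    keep = np.setdiff1d(np.arange(n), removed)
    removed_names = (
        [cloud.names[i] for i in removed] if cloud.names is not None
        else [str(i) for i in removed]
    )
    return cloud.subset(keep), removed_names


def bio_noise(
    cloud: NeuronPointCloud, spec: BioNoiseSpec
) -> tuple[NeuronPointCloud, DeformationParams]:
    """Deform the cloud by a random Gaussian-mixture displacement field.

    Centers are uniform over the cloud's bounding box; each displacement
    has an isotropic random direction and fixed magnitude ``amplitude``
    (or, with ``gaussian_magnitude``, is drawn from N(0, σ²I)).
    """
    rng = np.random.default_rng(spec.seed)
    lo = cloud.positions.min(axis=0)
    hi = cloud.positions.max(axis=0)
    centers = rng.uniform(lo, hi, size=(spec.n_centers, 3))
    if spec.gaussian_magnitude:
        disp = rng.normal(0.0, spec.sigma, size=(spec.n_centers, 3))
    else:
        dirs = rng.normal(size=(spec.n_centers, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        disp = dirs * spec.amplitude
    params = DeformationParams(disp, centers, spec.sigma)
    return cloud.with_positions(deformation_apply(params, cloud.positions)), params


def assign_random_colors(
    cloud_a: NeuronPointCloud,
    cloud_b: NeuronPointCloud,
    k: int,
    seed: int = 0,
    unique: bool = False,
) -> tuple[NeuronPointCloud, NeuronPointCloud]:
    """Give each neuron NAME a random color in {0..k−1}, identically in both
    clouds.  With ``unique`` (requires k ≥ number of names) every name gets
    its own color."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if cloud_a.names is None or cloud_b.names is None:
        raise ValidationError("color assignment needs labeled clouds")
    names = sorted(set(cloud_a.names) | set(cloud_b.names))
    if set(cloud_a.names) != set(cloud_b.names):
        raise ValidationError("clouds must share the same neuron name set")
    rng = np.random.default_rng(seed)
    if unique:
        if k < len(names):
            raise ValidationError("unique coloring needs k >= number of neurons")
        perm = rng.permutation(len(names))
        mapping = {n: int(perm[i]) for i, n in enumerate(names)}
    else:
        draws = rng.integers(0, k, size=len(names))
        mapping = {n: int(draws[i]) for i, n in enumerate(names)}
    out_a = cloud_a.copy()
    out_a.colors = np.array([mapping[n] for n in cloud_a.names])
    out_b = cloud_b.copy()
    out_b.colors = np.array([mapping[n] for n in cloud_b.names])
    return out_a, out_b


# ---------------------------------------------------------------------------
# synthetic worm fixture
# ---------------------------------------------------------------------------

@dataclass
class WormSpec:
    """Morphology of a synthetic worm fixture.

    A tube of length ``length`` μm bent along a circular arc of total turn
    ``bend_angle`` radians, with half-width ``half_width`` μm tapering to
    pointed tips over the outer ``taper_frac`` of the body at each end.
    ``n_neurons`` somata are placed inside, densified in the head and tail
    (fractions ``head_frac`` of the arc length holding ``head_weight`` of
    the neurons, mirrored for the tail) to emulate the head/tail ganglia and
    the sparse midbody cord.
    """

    length: float = 800.0
    half_width: float = 40.0
    bend_angle: float = 0.0  # radians of total spine turn; 0 = straight
    taper_frac: float = 0.12
    n_neurons: int = 300
    head_frac: float = 0.2
    head_weight: float = 0.55
    tail_frac: float = 0.15
    tail_weight: float = 0.2
    z_half: float = 15.0  # vertical half-extent of soma placement, μm
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.bend_angle != 0.0:
            radius = self.length / abs(self.bend_angle)
            if self.half_width >= radius:
                raise ValidationError("width exceeds bend radius; hull self-intersects")


def _spine(spec: WormSpec, arc: np.ndarray) -> np.ndarray:
    """Spine points at the given arc lengths, starting at the origin heading +x."""
    if spec.bend_angle == 0.0:
        return np.column_stack([arc, np.zeros_like(arc)])
    R = spec.length / spec.bend_angle  # signed radius
    theta = arc / R
    return np.column_stack([R * np.sin(theta), R * (1.0 - np.cos(theta))])


def _half_width_profile(spec: WormSpec, arc: np.ndarray) -> np.ndarray:
    """Tapered half-width: full in the trunk, elliptical taper to 0 at tips."""
    u = arc / spec.length
    w = np.full_like(u, spec.half_width)
    tf = spec.taper_frac
    head = u < tf
    w[head] = spec.half_width * np.sqrt(np.clip(u[head] / tf, 0, 1) * (2 - u[head] / tf))
    tail = u > 1 - tf
    v = (1 - u[tail]) / tf
    w[tail] = spec.half_width * np.sqrt(np.clip(v, 0, 1) * (2 - v))
    return w


def synth_worm(
    spec: WormSpec | None = None, seed: int = 0, names: Sequence[str] | None = None
) -> tuple[HullMask, NeuronPointCloud, NeuronPointCloud]:
    """Generate (hull mask, raw labeled cloud, ground-truth canonical cloud).

    The ground-truth canonical positions are (spine arc length, signed
    perpendicular offset, z), isotropically rescaled so that the neuron
    x-range spans [0, 800] μm — the same convention the straightener uses.
    """
    spec = spec or WormSpec()
    rng = np.random.default_rng(seed)

    # --- neuron placement in intrinsic (arc, offset, z) coordinates
    n = spec.n_neurons
    region = rng.choice(
        3, size=n,
        p=[spec.head_weight, 1 - spec.head_weight - spec.tail_weight, spec.tail_weight],
    )
    lo_margin = 0.02 * spec.length
    arc = np.empty(n)
    for i, r in enumerate(region):
        if r == 0:
            arc[i] = rng.uniform(lo_margin, spec.head_frac * spec.length)
        elif r == 2:
            arc[i] = rng.uniform((1 - spec.tail_frac) * spec.length,
                                 spec.length - lo_margin)
        else:
            arc[i] = rng.uniform(spec.head_frac * spec.length,
                                 (1 - spec.tail_frac) * spec.length)
    arc.sort()
    hw = _half_width_profile(spec, arc)
    offset = rng.uniform(-0.7, 0.7, size=n) * hw
    z = rng.uniform(-1, 1, size=n) * np.minimum(spec.z_half, 0.7 * hw)

    if names is None:
        pool = neuron_name_list(exclude_can=True)
        if n <= len(pool):
            names = pool[:n]
        else:
            names = pool + [f"SYN{i}" for i in range(n - len(pool))]
    names = list(names)[:n]

    # --- embed in the bent frame
    dense_arc = np.linspace(0.0, spec.length, 2048)
    sp = _spine(spec, dense_arc)
    tangent = np.gradient(sp, dense_arc, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    spine_xy = np.column_stack([
        np.interp(arc, dense_arc, sp[:, 0]), np.interp(arc, dense_arc, sp[:, 1])
    ])
    nrm = np.column_stack([
        np.interp(arc, dense_arc, normal[:, 0]), np.interp(arc, dense_arc, normal[:, 1])
    ])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    raw_xy = spine_xy + nrm * offset[:, None]
    raw = NeuronPointCloud(np.column_stack([raw_xy, z]), names)

    # --- ground-truth canonical frame
    gt = np.column_stack([arc, offset, z])
    x0 = gt[:, 0].min()
    scale = 800.0 / (gt[:, 0].max() - x0)
    gt[:, 0] = (gt[:, 0] - x0) * scale
    gt[:, 1] *= scale
    gt[:, 2] *= scale
    truth = NeuronPointCloud(gt, list(names), frame=CANONICAL)

    # --- rasterize the hull
    px = spec.pixel_size
    hw_dense = _half_width_profile(spec, dense_arc)
    pad = 4 * px + spec.half_width
    xmin, ymin = sp.min(axis=0) - pad
    xmax, ymax = sp.max(axis=0) + pad
    nx = int(np.ceil((xmax - xmin) / px)) + 1
    ny = int(np.ceil((ymax - ymin) / px)) + 1
    xs = xmin + np.arange(nx) * px
    ys = ymin + np.arange(ny) * px
    from scipy.spatial import cKDTree

    tree = cKDTree(sp)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    dist, idx = tree.query(pts, k=1)
    grid = (dist <= hw_dense[idx]).reshape(ny, nx)
    mask = HullMask(grid, px)
    # raw cloud shares the mask's coordinate frame (origin at pixel [0,0])
    raw_shifted = raw.with_positions(
        raw.positions - np.array([xmin, ymin, 0.0])
    )
    return mask, raw_shifted, truth
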