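"""Generalized-mean (GM) point-cloud alignment and greedy ID assignment.

The GM loss scores a moving (unlabeled) cloud against a reference (atlas)
cloud: for each unlabeled neuron j, the power mean with negative exponent γ
of its distances to all same-color reference neurons,

    ℓ = Σ_j ( Σ_i δ(c_i, c_j) |r_i − x_j|^γ / Σ_i δ(c_i, c_j) )^(1/γ),

summed over the moving cloud.  With γ < 0 the mean is dominated by the
smallest distances, which encourages pairing while — unlike a hard minimum
(the γ → −∞ limit) — keeping gradient flow from runner-up candidates, so the
descent can escape poor initial pairings.  γ = −6 is the default balance.

Two descent parameterizations are provided:

* free positions ("GM"): every moving position is an independent parameter;
* a Gaussian-mixture deformation field ("GM Realistic"): the moving cloud is
  displaced by f(r) = Σ_n d_n exp(−|r − (r_n + s)|² / 2σ²), and descent runs
  over the 6N+1 field parameters (displacements d_n, centers r_n, width σ)
  plus the redundant global center shift s.  This restricts the fit to
  smooth, biologically plausible deformations where neighboring neurons move
  coherently.

Distances are floored at a small ε to keep |r|^γ finite at contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import distance
from sklearn.base import BaseEstimator

from .io import Atlas, NeuronPointCloud, ValidationError


@dataclass
class GMConfig:
    """Hyperparameters of the GM descent.

    gamma < 0 is the generalized-mean exponent; epsilon the distance floor in
    μm; learning_rate the initial line-search step; convergence_tol the
    relative loss-change threshold.
    """

    gamma: float = -6.0
    epsilon: float = 1e-3
    learning_rate: float = 1.0
    max_iters: int = 2000
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma >= 0 and self.gamma != 2.0:
            # gamma=2 is admitted for the Gaussian-mixture-likelihood check
            raise ValidationError("gamma must be negative")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.max_iters < 1:
            raise ValidationError("max_iters must be >= 1")


def _color_classes(c1: np.ndarray | None, c2: np.ndarray | None,
                   n1: int, n2: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pair up index sets (reference, moving) per shared color class."""
    if c1 is None and c2 is None:
        return [(np.arange(n1), np.arange(n2))]
    if (c1 is None) != (c2 is None):
        raise ValidationError("colors must be given for both clouds or neither")
    missing = sorted(set(np.unique(c2)) - set(np.unique(c1)))
    if missing:
        raise ValidationError(
            f"unlabeled colors absent from the labeled cloud: {missing}"
        )
    out = []
    for col in np.unique(c2):
        out.append((np.nonzero(c1 == col)[0], np.nonzero(c2 == col)[0]))
    return out


def _gm_rows(D: np.ndarray, gamma: float, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-row generalized mean of a floored distance matrix, with the
    per-element weights w_ij = ∂g_i/∂d_ij, computed in overflow-safe form."""
    Df = np.maximum(D, eps)
    mu = Df.min(axis=1, keepdims=True)
    ratio = Df / mu
    m = D.shape[1]
    A = np.mean(ratio ** gamma, axis=1, keepdims=True)
    g = (mu * A ** (1.0 / gamma))[:, 0]
    W = (A ** ((1.0 - gamma) / gamma)) * ratio ** (gamma - 1.0) / m
    W[D < eps] = 0.0  # floored distances carry no gradient
    return g, W


def gm_loss(
    r1: np.ndarray,
    r2: np.ndarray,
    c1: np.ndarray | None = None,
    c2: np.ndarray | None = None,
    gamma: float = -6.0,
    epsilon: float = 1e-3,
) -> float:
    """The GM alignment loss between labeled r1 and moving r2 positions (μm)."""
    r1 = np.asarray(r1, dtype=float).reshape(-1, 3)
    r2 = np.asarray(r2, dtype=float).reshape(-1, 3)
    total = 0.0
    for idx1, idx2 in _color_classes(c1, c2, len(r1), len(r2)):
        if len(idx2) == 0:
            continue
        if len(idx1) == 0:
            raise ValidationError("a moving color class has no labeled partner")
        D = np.maximum(distance.cdist(r2[idx2], r1[idx1]), epsilon)
        mu = D.min(axis=1, keepdims=True)
        A = np.mean((D / mu) ** gamma, axis=1)
        total += float((mu[:, 0] * A ** (1.0 / gamma)).sum())
    return total


def gm_loss_grad(
    r1: np.ndarray,
    r2: np.ndarray,
    c1: np.ndarray | None = None,
    c2: np.ndarray | None = None,
    gamma: float = -6.0,
    epsilon: float = 1e-3,
) -> tuple[float, np.ndarray]:
    """GM loss and its analytic gradient with respect to the moving positions."""
    r1 = np.asarray(r1, dtype=float).reshape(-1, 3)
    r2 = np.asarray(r2, dtype=float).reshape(-1, 3)
    grad = np.zeros_like(r2)
    total = 0.0
    for idx1, idx2 in _color_classes(c1, c2, len(r1), len(r2)):
        if len(idx2) == 0:
            continue
        if len(idx1) == 0:
            raise ValidationError("a moving color class has no labeled partner")
        D = distance.cdist(r2[idx2], r1[idx1])
        g, W = _gm_rows(D, gamma, epsilon)
        total += float(g.sum())
        Df = np.maximum(D, epsilon)
        diff = r2[idx2][:, None, :] - r1[idx1][None, :, :]
        grad[idx2] = np.einsum("ij,ijk->ik", W / Df, diff)
    return total, grad


# ---------------------------------------------------------------------------
# deformation field
# ---------------------------------------------------------------------------

@dataclass
class DeformationParams:
    """Gaussian-mixture deformation field parameters (6N+1 plus global shift).

    ``displacements`` d_n and ``centers`` r_n are (N, 3) in μm, ``sigma`` the
    shared influence radius; ``global_shift`` s translates all centers
    jointly (redundant with the centers, kept for numerical stability).
    """

    displacements: np.ndarray
    centers: np.ndarray
    sigma: float
    global_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(-1, 3)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.global_shift = np.asarray(self.global_shift, dtype=float).reshape(3)
        if len(self.displacements) != len(self.centers):
            raise ValidationError("displacements/centers length mismatch")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.displacements.ravel(), self.centers.ravel(),
            [np.log(self.sigma)], self.global_shift,
        ])

    @classmethod
    def from_vector(cls, v: np.ndarray, n: int) -> "DeformationParams":
        d = v[: 3 * n].reshape(n, 3)
        c = v[3 * n: 6 * n].reshape(n, 3)
        return cls(d, c, float(np.exp(v[6 * n])), v[6 * n + 1:])


def deformation_apply(params: DeformationParams, positions: np.ndarray) -> np.ndarray:
    """Displace positions by the Gaussian-mixture field f(r)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    diff = positions[:, None, :] - (params.centers + params.global_shift)[None, :, :]
    E = np.exp(-np.sum(diff ** 2, axis=2) / (2.0 * params.sigma ** 2))
    return positions + E @ params.displacements


def _deformation_loss_grad(
    v: np.ndarray, n: int, base: np.ndarray,
    r1: np.ndarray, c1, c2, gamma: float, epsilon: float, ridge: float,
) -> tuple[float, np.ndarray]:
    """Loss and gradient in the 6N+4 parameter vector (σ in log-space)."""
    p = DeformationParams.from_vector(v, n)
    diff = base[:, None, :] - (p.centers + p.global_shift)[None, :, :]
    sq = np.sum(diff ** 2, axis=2)
    E = np.exp(-sq / (2.0 * p.sigma ** 2))
    x = base + E @ p.displacements
    loss, G = gm_loss_grad(r1, x, c1, c2, gamma, epsilon)
    grad_d = E.T @ G
    a = G @ p.displacements.T  # (n_pts, N): d_n · G_j
    coef = E * a
    grad_centers = np.einsum("jn,jnk->nk", coef, diff) / p.sigma ** 2
    grad_shift = grad_centers.sum(axis=0)
    grad_sigma = float(np.sum(coef * sq)) / p.sigma ** 3
    if ridge > 0:
        loss += ridge * float(np.sum(p.displacements ** 2))
        grad_d = grad_d + 2.0 * ridge * p.displacements
    g = np.concatenate([
        grad_d.ravel(), grad_centers.ravel(),
        [grad_sigma * p.sigma],  # chain rule through log σ
        grad_shift,
    ])
    return loss, g


# ---------------------------------------------------------------------------
# descent
# ---------------------------------------------------------------------------

class DivergenceError(RuntimeError):
    pass


def _gradient_descent(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    learning_rate: float,
    max_iters: int,
    tol: float,
    fun: Callable[[np.ndarray], float] | None = None,
    patience: int = 10,
) -> tuple[np.ndarray, list[float]]:
    """Full-batch gradient descent with backtracking line search.

    The step (a length along the normalized descent direction) is halved
    until the loss strictly decreases, so the returned trace is monotonically
    non-increasing; the accepted step, doubled, seeds the next iteration.
    ``fun`` is an optional cheap loss-only evaluation used inside the line
    search.  Convergence: relative loss decrease below ``tol`` for
    ``patience`` consecutive iterations.
    """
    if fun is None:
        fun = lambda x: fun_grad(x)[0]  # noqa: E731
    x = np.asarray(x0, dtype=float).copy()
    f, g = fun_grad(x)
    if not np.isfinite(f):
        raise DivergenceError("loss not finite at initialization")
    trace = [f]
    step = learning_rate
    stall = 0
    for it in range(max_iters):
        gnorm = np.linalg.norm(g)
        if gnorm == 0:
            break
        direction = g / gnorm
        accepted = False
        while step > 1e-12 * learning_rate:
            x_new = x - step * direction
            f_new = fun(x_new)
            if np.isnan(f_new):
                raise DivergenceError(f"loss became NaN at iteration {it}")
            if f_new < f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (f - f_new) / max(abs(f), 1e-300)
        x = x_new
        f, g = fun_grad(x)
        trace.append(f)
        step = min(step * 2.0, learning_rate * 64.0)
        stall = stall + 1 if rel < tol else 0
        if stall >= patience:
            break
    return x, trace


def _as_positions_colors(obj) -> tuple[np.ndarray, np.ndarray | None, list[str] | None]:
    if isinstance(obj, Atlas):
        return obj.positions, obj.colors, list(obj.names)
    if isinstance(obj, NeuronPointCloud):
        return obj.positions, obj.colors, obj.names
    arr = np.asarray(obj, dtype=float).reshape(-1, 3)
    return arr, None, None


def align_gm(
    unlabeled, atlas, config: GMConfig | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Free-position GM descent: move every unlabeled position independently."""
    cfg = config or GMConfig()
    r2, c2, _ = _as_positions_colors(unlabeled)
    r1, c1, _ = _as_positions_colors(atlas)
    if c2 is not None and c1 is None:
        c2 = None  # reference carries no colors: fall back to color-free loss

    def fg_flat(x):
        f, g = gm_loss_grad(r1, x.reshape(-1, 3), c1, c2, cfg.gamma, cfg.epsilon)
        return f, g.ravel()

    def f_only(x):
        return gm_loss(r1, x.reshape(-1, 3), c1, c2, cfg.gamma, cfg.epsilon)

    x, trace = _gradient_descent(
        fg_flat, r2.ravel(), cfg.learning_rate, cfg.max_iters, cfg.convergence_tol,
        fun=f_only,
    )
    return x.reshape(-1, 3), trace


def init_deformation(
    positions: np.ndarray, atlas_positions: np.ndarray, n_centers: int
) -> DeformationParams:
    """Default field initialization: zero displacements, centers on a uniform
    grid over the moving cloud's bounding box (grid shape proportioned to the
    box), σ = ¼ of the box diagonal, global shift = centroid difference."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    lo, hi = positions.min(axis=0), positions.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    # choose per-axis grid counts with product >= n_centers, proportioned to span
    weights = span / span.max()
    base = (n_centers / np.prod(weights)) ** (1.0 / 3.0)
    counts = np.maximum(1, np.round(base * weights).astype(int))
    while np.prod(counts) < n_centers:
        counts[np.argmax(span / counts)] += 1
    axes = [np.linspace(lo[k], hi[k], counts[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(grid) > n_centers:
        # keep the grid nodes nearest to actual neurons
        d = distance.cdist(grid, positions).min(axis=1)
        grid = grid[np.argsort(d)[:n_centers]]
    sigma = 0.25 * float(np.linalg.norm(span))
    # zero displacements and zero center shift: the canonical frames of the
    # two clouds already roughly agree, and a centroid-matching start would
    # mis-position a cropped moving cloud against a whole-body reference
    return DeformationParams(np.zeros_like(grid), grid, sigma, np.zeros(3))


def align_gm_realistic(
    unlabeled, atlas,
    config: GMConfig | None = None,
    n_centers: int = 64,
    ridge: float = 0.0,
    init: DeformationParams | None = None,
) -> tuple[np.ndarray, DeformationParams, list[float]]:
    """GM descent over the Gaussian-mixture deformation-field parameters.

    The moving positions are re-parameterized as x = r + f(r); descent runs
    over the field's displacements, centers, σ (in log-space) and global
    center shift.  ``ridge`` adds an optional quadratic penalty on the
    displacement magnitudes (off by default).
    """
    cfg = config or GMConfig()
    r2, c2, _ = _as_positions_colors(unlabeled)
    r1, c1, _ = _as_positions_colors(atlas)
    if c2 is not None and c1 is None:
        c2 = None
    if len(r2) == 0:
        raise ValidationError("cannot align an empty cloud")
    p0 = init if init is not None else init_deformation(r2, r1, n_centers)
    n = p0.n_centers

    def fg(v):
        return _deformation_loss_grad(v, n, r2, r1, c1, c2, cfg.gamma, cfg.epsilon, ridge)

    def f_only(v):
        p = DeformationParams.from_vector(v, n)
        x = deformation_apply(p, r2)
        f = gm_loss(r1, x, c1, c2, cfg.gamma, cfg.epsilon)
        if ridge > 0:
            f += ridge * float(np.sum(p.displacements ** 2))
        return f

    v, trace = _gradient_descent(
        fg, p0.to_vector(), cfg.learning_rate, cfg.max_iters, cfg.convergence_tol,
        fun=f_only,
    )
    params = DeformationParams.from_vector(v, n)
    return deformation_apply(params, r2), params, trace


# ---------------------------------------------------------------------------
# greedy color-constrained assignment
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    """Unlabeled-index → atlas-name mapping with match distances (μm)."""

    pairs: dict[int, tuple[str, float]]
    unmatched: set[int]

    def names(self, n: int | None = None) -> list[str | None]:
        size = n if n is not None else (max(self.pairs) + 1 if self.pairs else 0)
        out: list[str | None] = [None] * size
        for i, (name, _) in self.pairs.items():
            out[i] = name
        return out


def assign_ids(
    transformed: np.ndarray,
    atlas,
    colors: np.ndarray | None = None,
) -> Assignment:
    """Greedy global-minimum ID assignment with row/column deletion.

    Builds the matrix of pairwise distances between moving neurons and atlas
    entries, repeatedly takes its smallest element (ties broken by lowest
    row, then column), records that pairing and deletes the row and column.
    When colors are given on both sides, only same-color pairings are
    admissible; moving neurons left without an admissible partner end up in
    ``unmatched``.
    """
    transformed = np.asarray(transformed, dtype=float).reshape(-1, 3)
    r1, c1, names = _as_positions_colors(atlas)
    if names is None:
        names = [str(i) for i in range(len(r1))]
    D = distance.cdist(transformed, r1)
    if colors is not None and c1 is not None:
        colors = np.asarray(colors).reshape(-1)
        D = D.copy()
        D[colors[:, None] != np.asarray(c1)[None, :]] = np.inf
    pairs = {
        i: (names[j], d) for i, j, d in greedy_min_assignment(D)
    }
    unmatched = set(range(len(transformed))) - set(pairs)
    return Assignment(pairs, unmatched)


def greedy_min_assignment(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Iterated global-minimum selection on a cost matrix.

    Repeatedly locates the smallest element (ties broken by lowest row, then
    lowest column — ``argmin``'s row-major order), records (row, col, cost)
    and deletes that row and column; infinite entries are inadmissible.
    """
    work = np.asarray(D, dtype=float).copy()
    out: list[tuple[int, int, float]] = []
    for _ in range(min(work.shape)):
        flat = np.argmin(work)
        i, j = np.unravel_index(flat, work.shape)
        if not np.isfinite(work[i, j]):
            break
        out.append((int(i), int(j), float(work[i, j])))
        work[i, :] = np.inf
        work[:, j] = np.inf
    return out


# ---------------------------------------------------------------------------
# estimators and the aligner registry
# ---------------------------------------------------------------------------

class GeneralizedMeanAligner(BaseEstimator):
    """GM alignment with free per-neuron positions (scikit-learn style).

    ``fit(X, y)`` aligns the moving cloud ``X`` to the reference ``y``
    (an :class:`Atlas` or labeled cloud); ``predict(X)`` returns the greedy
    ID assignment of the fitted positions.

    Attributes
    ----------
    transformed_ : (n, 3) ndarray
        Moving positions after descent.
    loss_trace_ : list of float
        Monotone loss trace.
    """

    def __init__(self, gamma: float = -6.0, epsilon: float = 1e-3,
                 learning_rate: float = 1.0, max_iters: int = 2000,
                 convergence_tol: float = 1e-6, seed: int = 0):
        self.gamma = gamma
        self.epsilon = epsilon
        self.learning_rate = learning_rate
        self.max_iters = max_iters
        self.convergence_tol = convergence_tol
        self.seed = seed

    def _config(self) -> GMConfig:
        return GMConfig(self.gamma, self.epsilon, self.learning_rate,
                        self.max_iters, self.convergence_tol, self.seed)

    def fit(self, X, y) -> "GeneralizedMeanAligner":
        self.reference_ = y
        self.transformed_, self.loss_trace_ = align_gm(X, y, self._config())
        return self

    def predict(self, X=None) -> Assignment:
        if not hasattr(self, "transformed_"):
            raise RuntimeError("aligner is not fitted")
        _, c2, _ = _as_positions_colors(X) if X is not None else (None, None, None)
        return assign_ids(self.transformed_, self.reference_, colors=c2)

    def fit_predict(self, X, y) -> Assignment:
        return self.fit(X, y).predict(X)


class GMRealisticAligner(GeneralizedMeanAligner):
    """GM alignment through the Gaussian-mixture deformation field.

    Adds ``n_centers`` (field resolution) and ``ridge`` (optional quadratic
    displacement penalty) to the base hyperparameters; exposes the fitted
    field as ``deformation_params_``.
    """

    def __init__(self, gamma: float = -6.0, epsilon: float = 1e-3,
                 learning_rate: float = 1.0, max_iters: int = 2000,
                 convergence_tol: float = 1e-6, seed: int = 0,
                 n_centers: int = 64, ridge: float = 0.0):
        super().__init__(gamma, epsilon, learning_rate, max_iters,
                         convergence_tol, seed)
        self.n_centers = n_centers
        self.ridge = ridge

    def fit(self, X, y) -> "GMRealisticAligner":
        self.reference_ = y
        self.transformed_, self.deformation_params_, self.loss_trace_ = \
            align_gm_realistic(X, y, self._config(),
                               n_centers=self.n_centers, ridge=self.ridge)
        return self


_REGISTRY: dict[str, Callable[..., GeneralizedMeanAligner]] = {
    "gm": GeneralizedMeanAligner,
    "gm-realistic": GMRealisticAligner,
}


def register_aligner(name: str, factory: Callable[..., object]) -> None:
    """Register an external alignment routine (e.g. a CPD implementation)
    under a name usable by the benchmark harness.  The factory must return an
    object with ``fit(X, y)``, ``transformed_`` and ``predict``."""
    _REGISTRY[name] = factory


def get_aligner(name: str, **kwargs):
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown aligner {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**kwargs)


def registered_aligners() -> list[str]:
    return sorted(_REGISTRY)
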