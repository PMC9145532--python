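"""Accuracy-vs-perturbation experiment harness.

Reproduces the validation protocol for the aligners: start from a
ground-truth cloud, apply a scenario-specific perturbation (cropping with
size imbalance, random dropout, smooth biological deformation, or a
randomized-color sweep) plus a shared rigid jitter of the reference copy,
align, greedily assign IDs, and score the fraction of correct identities.
Each sweep point is repeated over independent seeds and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Assignment, assign_ids, get_aligner
from .io import NeuronPointCloud, ValidationError
from .simulate import (
    BioNoiseSpec, assign_random_colors, bio_noise, crop_cloud, dropout, rigid_jitter,
)

SCENARIOS = ("cropping", "dropout", "bionoise", "color_sweep")


@dataclass
class ExperimentSpec:
    """One accuracy-vs-perturbation study.

    ``sweep`` holds the scenario's swept values: crop thresholds (μm) for
    cropping, neurons removed for dropout, influence radii σ (μm) for
    bionoise, color counts k for color_sweep.
    """

    scenario: str
    sweep: Sequence[float]
    substrate: NeuronPointCloud
    methods: Sequence[str] = ("gm-realistic",)
    n_reps: int = 40
    seed: int = 0
    max_jitter: float = 5.0
    bio_amplitude: float = 6.1
    bio_centers: int = 100
    method_params: Mapping[str, Mapping] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if len(self.sweep) == 0:
            raise ValidationError("sweep must be non-empty")
        if self.substrate.names is None:
            raise ValidationError("substrate cloud must be labeled")


def accuracy(assignment: Assignment, truth: Mapping[int, str], n_total: int | None = None) -> float:
    """Fraction of unlabeled neurons assigned their true identity.

    ``truth`` maps unlabeled index → true name; unmatched neurons count as
    incorrect.
    """
    if not truth:
        raise ValidationError("cannot score an empty cloud")
    n = n_total if n_total is not None else len(truth)
    correct = sum(
        1 for i, name in truth.items()
        if i in assignment.pairs and assignment.pairs[i][0] == name
    )
    return correct / n


def rescale_extent(cloud: NeuronPointCloud, lo: float, hi: float) -> NeuronPointCloud:
    """Isotropically rescale so the x-range spans [lo, hi] (y, z share the factor)."""
    pos = cloud.positions.copy()
    x0 = pos[:, 0].min()
    span = pos[:, 0].max() - x0
    scale = (hi - lo) / span if span > 0 else 1.0
    pos[:, 0] = lo + (pos[:, 0] - x0) * scale
    pos[:, 1] *= scale
    pos[:, 2] *= scale
    return cloud.with_positions(pos)


def _align_and_assign(method: str, unlabeled: NeuronPointCloud,
                      reference: NeuronPointCloud,
                      params: Mapping | None = None) -> Assignment:
    """Run one aligner and greedily assign IDs.

    The GM methods consume the color indices natively through the loss's
    color indicator.  Other (plug-in) methods are run once per color class on
    the restricted point sets and the assignments are combined.
    """
    params = dict(params or {})
    use_native_colors = method.startswith("gm")
    if unlabeled.colors is None or use_native_colors:
        aligner = get_aligner(method, **params)
        aligner.fit(unlabeled, reference)
        return assign_ids(aligner.transformed_, reference, colors=unlabeled.colors)
    # per-color runs for color-unaware baselines
    pairs: dict[int, tuple[str, float]] = {}
    unmatched: set[int] = set()
    for col in np.unique(unlabeled.colors):
        sub_idx = np.nonzero(unlabeled.colors == col)[0]
        ref_idx = np.nonzero(reference.colors == col)[0]
        if len(ref_idx) == 0:
            unmatched |= set(int(i) for i in sub_idx)
            continue
        sub = unlabeled.subset(sub_idx)
        ref = reference.subset(ref_idx)
        aligner = get_aligner(method, **params)
        aligner.fit(sub, ref)
        a = assign_ids(aligner.transformed_, ref)
        for local_i, (name, d) in a.pairs.items():
            pairs[int(sub_idx[local_i])] = (name, d)
        unmatched |= {int(sub_idx[i]) for i in a.unmatched}
    return Assignment(pairs, unmatched)


def _one_rep(spec: ExperimentSpec, value: float, rep: int, method: str) -> float:
    seed = spec.seed + rep
    substrate = spec.substrate

    if spec.scenario == "cropping":
        substrate = rescale_extent(substrate, -600.0, 200.0)
        unlabeled = crop_cloud(substrate, "x", lo=0.0)
        reference = crop_cloud(substrate, "x", lo=float(value))
        reference, _ = rigid_jitter(reference, spec.max_jitter, seed)
    elif spec.scenario == "dropout":
        unlabeled, _ = dropout(substrate, int(value), seed)
        reference, _ = rigid_jitter(substrate.copy(), spec.max_jitter, seed + 10_000)
    elif spec.scenario == "bionoise":
        noise = BioNoiseSpec(n_centers=spec.bio_centers, amplitude=spec.bio_amplitude,
                             sigma=max(float(value), 1e-3), seed=seed)
        unlabeled, _ = bio_noise(substrate, noise)
        reference, _ = rigid_jitter(substrate.copy(), spec.max_jitter, seed + 10_000)
    elif spec.scenario == "color_sweep":
        unlabeled, _ = rigid_jitter(substrate.copy(), spec.max_jitter, seed)
        reference = substrate.copy()
        k = int(value)
        unlabeled, reference = assign_random_colors(
            unlabeled, reference, k, seed=seed + 20_000,
            unique=(k >= len(substrate)),
        )
    else:  # pragma: no cover
        raise ValidationError(spec.scenario)

    assignment = _align_and_assign(method, unlabeled, reference,
                                   spec.method_params.get(method))
    truth = {i: name for i, name in enumerate(unlabeled.names)}
    return accuracy(assignment, truth)


def run_experiment(spec: ExperimentSpec, progress: bool = False) -> pd.DataFrame:
    """Run a full sweep; returns columns
    ``method, sweep_value, mean_accuracy, stderr, n_reps``."""
    rows = []
    for method in spec.methods:
        get_aligner(method)  # fail fast on unknown names
        for value in spec.sweep:
            accs = np.array([
                _one_rep(spec, value, rep, method) for rep in range(spec.n_reps)
            ])
            rows.append({
                "method": method,
                "sweep_value": value,
                "mean_accuracy": accs.mean(),
                "stderr": accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0,
                "n_reps": spec.n_reps,
            })
            if progress:
                print(f"{method} @ {value}: {accs.mean():.3f}")
    return pd.DataFrame(rows)


def tune_hyperparameters(
    objective: Callable[[Mapping[str, float]], float],
    space: Mapping[str, tuple[float, float]],
    budget: int,
    seed: int = 0,
    local_tol: float = 1e-3,
) -> tuple[dict[str, float], list[tuple[dict[str, float], float]]]:
    """Maximize ``objective`` by random search followed by local search.

    ``budget`` uniform draws over the box ``space`` pick the incumbent, then
    a coordinate-wise local search perturbs one parameter at a time with a
    step that halves whenever neither direction improves, stopping below
    ``local_tol`` of the parameter's range.  Deterministic for a fixed seed.
    Returns the best parameter set and the evaluation trace.
    """
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(space)
    trace: list[tuple[dict[str, float], float]] = []
    best, best_score = None, -np.inf
    for _ in range(budget):
        params = {k: float(rng.uniform(*space[k])) for k in names}
        score = objective(params)
        trace.append((params, score))
        if score > best_score:
            best, best_score = dict(params), score
    steps = {k: (space[k][1] - space[k][0]) / 4.0 for k in names}
    improved = True
    while improved and any(
        steps[k] > local_tol * (space[k][1] - space[k][0]) for k in names
    ):
        improved = False
        for k in names:
            for direction in (+1.0, -1.0):
                cand = dict(best)
                cand[k] = float(np.clip(cand[k] + direction * steps[k], *space[k]))
                if cand[k] == best[k]:
                    continue
                score = objective(cand)
                trace.append((cand, score))
                if score > best_score:
                    best, best_score = cand, score
                    improved = True
        if not improved:
            for k in names:
                steps[k] *= 0.5
            improved = any(
                steps[k] > local_tol * (space[k][1] - space[k][0]) for k in names
            )
            if improved:
                improved = True  # continue halved-step sweep
            else:
                break
    return best, trace
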