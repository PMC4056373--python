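"""Generative simulator of the paired double-mutant screening pipeline.

The simulated measurement model is multiplicative: an observed colony size
is a plate growth constant times the two single-mutant fitnesses, perturbed
on the log (residual) scale by a static interaction effect, an optional
differential effect active only in the treatment condition, and two noise
components::

    z = base_size * p_qic * f_qc * f_ac
        * exp(e_qa + delta_qa * 1[c == treatment] + u_qai + v_qaic)

The key structural feature is the noise split: ``u_qai`` is drawn once per
(query, array, pipeline replicate) and reused in *both* conditions —
mimicking the experimental pipeline in which a single stream of plates is
split onto treated and untreated media at the last step — while ``v_qaic``
is condition-specific. Shared noise cancels in across-condition residual
differences, so the differential variance is ~2*sigma_cond**2 regardless of
sigma_shared, while static residual variance is ~sigma_shared**2 +
sigma_cond**2. This is the dependence structure that motivates paired
differential scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dgi.io import ColonyTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_experiment",
    "independent_normal_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated paired screen.

    Noise magnitudes are log-scale standard deviations; ``effect_size`` is
    the magnitude of injected differential effects on the residual (log)
    scale. ``conditions`` is (reference, treatment), in that order.
    """

    n_queries: int = 20
    n_arrays: int = 100
    n_replicates: int = 6
    conditions: tuple[str, str] = ("UT", "MMS")
    plate_shape: tuple[int, int] = (16, 24)
    plate_effect_sd: float = 0.1
    fitness_sd: float = 0.1
    condition_fitness_sd: float = 0.0
    sigma_shared: float = 0.15
    sigma_cond: float = 0.05
    interaction_frac: float = 0.0
    differential_frac: float = 0.0
    effect_size: float = 0.0
    base_size: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_queries, self.n_arrays, self.n_replicates) < 1:
            raise ValueError("n_queries, n_arrays, n_replicates must be >= 1")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("exactly two distinct conditions are required")
        for name in ("plate_effect_sd", "fitness_sd", "condition_fitness_sd",
                     "sigma_shared", "sigma_cond"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("interaction_frac", "differential_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.interaction_frac + self.differential_frac > 1.0:
            raise ValueError("static and differential pair fractions overlap")
        rows, cols = self.plate_shape
        if rows * cols < self.n_arrays:
            raise ValueError(
                f"plate_shape {self.plate_shape} holds {rows * cols} colonies "
                f"< n_arrays = {self.n_arrays}"
            )

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated screen.

    Effects for pairs not selected as static/differential are exactly zero
    and simply absent from the effect dicts.
    """

    config: SimulationConfig
    query_fitness: dict = field(default_factory=dict)  # (q, c) -> f
    array_fitness: dict = field(default_factory=dict)  # (a, c) -> f
    plate_effects: dict = field(default_factory=dict)  # plate_id -> p
    static_effects: dict = field(default_factory=dict)  # (q, a) -> e
    differential_effects: dict = field(default_factory=dict)  # (q, a) -> signed delta
    shared_noise: dict = field(default_factory=dict)  # (q, a, i) -> u
    cond_noise: dict = field(default_factory=dict)  # (q, a, i, c) -> v

    @property
    def differential_pairs(self) -> set:
        return set(self.differential_effects)

    @property
    def static_pairs(self) -> set:
        return set(self.static_effects)

    def to_json_dict(self) -> dict:
        def keyed(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else k: v
                    for k, v in d.items()}

        return {
            "config": {
                **{f: getattr(self.config, f) for f in (
                    "n_queries", "n_arrays", "n_replicates", "plate_effect_sd",
                    "fitness_sd", "condition_fitness_sd",
                    "sigma_shared", "sigma_cond", "interaction_frac",
                    "differential_frac", "effect_size", "base_size", "seed")},
                "conditions": list(self.config.conditions),
                "plate_shape": list(self.config.plate_shape),
            },
            "query_fitness": keyed(self.query_fitness),
            "array_fitness": keyed(self.array_fitness),
            "plate_effects": keyed(self.plate_effects),
            "static_effects": keyed(self.static_effects),
            "differential_effects": keyed(self.differential_effects),
        }


def _truncated_fitness(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    # fitness centered at 1; floor at 0.05 avoids degenerate (near-dead) strains
    return np.maximum(rng.normal(1.0, sd, size=n), 0.05)


def simulate_experiment(config: SimulationConfig):
    """Simulate a paired screen; returns ``(ColonyTable, SimulationTruth)``.

    Two plates are produced per (query, replicate) — one per condition —
    sharing the same per-replicate noise draws ``u``. Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nq, na, ni = config.n_queries, config.n_arrays, config.n_replicates
    ref, trt = config.reference, config.treatment
    queries = [f"Q{j + 1:03d}" for j in range(nq)]
    arrays = [f"A{j + 1:03d}" for j in range(na)]

    truth = SimulationTruth(config=config)

    # fitnesses: one baseline per gene, shared across conditions. A nonzero
    # condition_fitness_sd adds an independent per-condition deviation — a
    # single-mutant condition response, which is *not* a differential
    # interaction and is absorbed by the pooled array comparison downstream.
    fq = np.repeat(_truncated_fitness(rng, nq, config.fitness_sd)[:, None], 2, axis=1)
    fa = np.repeat(_truncated_fitness(rng, na, config.fitness_sd)[:, None], 2, axis=1)
    if config.condition_fitness_sd > 0:
        fq = np.maximum(fq + rng.normal(0, config.condition_fitness_sd, fq.shape), 0.05)
        fa = np.maximum(fa + rng.normal(0, config.condition_fitness_sd, fa.shape), 0.05)
    for j, q in enumerate(queries):
        truth.query_fitness[(q, ref)] = float(fq[j, 0])
        truth.query_fitness[(q, trt)] = float(fq[j, 1])
    for j, a in enumerate(arrays):
        truth.array_fitness[(a, ref)] = float(fa[j, 0])
        truth.array_fitness[(a, trt)] = float(fa[j, 1])

    # plate growth constants, one per (query, replicate, condition)
    plate_p = np.exp(rng.normal(0.0, config.plate_effect_sd, size=(nq, ni, 2)))

    # interaction pair assignment: differential pairs disjoint from static-only
    n_pairs = nq * na
    n_static = int(round(config.interaction_frac * n_pairs))
    n_diff = int(round(config.differential_frac * n_pairs))
    chosen = rng.choice(n_pairs, size=n_static + n_diff, replace=False)
    static_idx, diff_idx = chosen[:n_static], chosen[n_static:]
    e_static = np.zeros(n_pairs)
    if n_static:
        e_static[static_idx] = config.effect_size * rng.choice([-1.0, 1.0], n_static)
    delta = np.zeros(n_pairs)
    if n_diff:
        delta[diff_idx] = config.effect_size * rng.choice([-1.0, 1.0], n_diff)
    for flat in static_idx:
        truth.static_effects[(queries[flat // na], arrays[flat % na])] = float(
            e_static[flat]
        )
    for flat in diff_idx:
        truth.differential_effects[(queries[flat // na], arrays[flat % na])] = float(
            delta[flat]
        )

    # noise: u shared across conditions within a (q, a, i); v condition-specific
    u = rng.normal(0.0, config.sigma_shared, size=(nq, na, ni))
    v = rng.normal(0.0, config.sigma_cond, size=(nq, na, ni, 2))

    plate_cols = config.plate_shape[1]
    a_idx = np.arange(na)
    plate_row = a_idx // plate_cols + 1
    plate_col = a_idx % plate_cols + 1

    e_grid = e_static.reshape(nq, na)
    d_grid = delta.reshape(nq, na)

    frames = []
    for ci, cond in enumerate((ref, trt)):
        log_pert = (
            e_grid[:, :, None]
            + (d_grid[:, :, None] if cond == trt else 0.0)
            + u
            + v[:, :, :, ci]
        )
        # z[q, a, i]
        z = (
            config.base_size
            * plate_p[:, None, :, ci]
            * fq[:, None, None, ci]
            * fa[None, :, None, ci]
            * np.exp(log_pert)
        )
        qi, ai, ii = np.meshgrid(
            np.arange(nq), a_idx, np.arange(ni), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "query_id": np.array(queries)[qi.ravel()],
                    "array_id": np.array(arrays)[ai.ravel()],
                    "replicate": ii.ravel() + 1,
                    "condition": cond,
                    "plate_id": [
                        f"{queries[qq]}_r{rr + 1}_{cond}"
                        for qq, rr in zip(qi.ravel(), ii.ravel())
                    ],
                    "row": plate_row[ai.ravel()],
                    "col": plate_col[ai.ravel()],
                    "raw_size": z.ravel(),
                }
            )
        )

    for ci, cond in enumerate((ref, trt)):
        for j, q in enumerate(queries):
            for r in range(ni):
                truth.plate_effects[f"{q}_r{r + 1}_{cond}"] = float(plate_p[j, r, ci])
    for j, q in enumerate(queries):
        for k, a in enumerate(arrays):
            for r in range(ni):
                truth.shared_noise[(q, a, r + 1)] = float(u[j, k, r])
                truth.cond_noise[(q, a, r + 1, ref)] = float(v[j, k, r, 0])
                truth.cond_noise[(q, a, r + 1, trt)] = float(v[j, k, r, 1])

    table = ColonyTable(pd.concat(frames, ignore_index=True))
    return table, truth


def independent_normal_fixture(mu1, sigma1, mu2, sigma2, n, seed):
    """Paired draws from two independent normals and their differences.

    Under independence the differences are normal with mean ``mu1 - mu2``
    and variance ``sigma1**2 + sigma2**2`` — the additivity law the paired
    screen violates through shared noise.

    Returns ``(x1, x2, diffs)`` with ``diffs = x1 - x2``.
    """
    if sigma1 < 0 or sigma2 < 0:
        raise ValueError("sigmas must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    x1 = rng.normal(mu1, sigma1, size=n)
    x2 = rng.normal(mu2, sigma2, size=n)
    return x1, x2, x1 - x2
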