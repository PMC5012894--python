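"""Synthetic two-view data with known sparse latent structure.

The generator emulates the shape of an imaging + clinical-item study: a
wide view X (voxel-like) and a narrow view Y (item-like) share H latent
effects of strictly decreasing strength. Effect h contributes
``strength_h * t_h u_h*'`` to X and ``strength_h * t_h v_h*'`` to Y, where
``t_h`` is a standard-normal latent score per sample and ``u_h*``, ``v_h*``
are unit-norm weight vectors supported on small, by default disjoint,
feature subsets. Independent Gaussian noise is added to every entry, and
``H = 0`` yields a null regime with fully independent views. Optionally Y
is dichotomised to {1, 2} at per-feature medians, mimicking right/wrong
item coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TwoViewDataset

__all__ = ["SimulationSpec", "EffectTruth", "simulate", "support_f1"]


@dataclass(frozen=True)
class EffectTruth:
    """Ground truth for one planted effect."""

    u: np.ndarray
    v: np.ndarray
    strength: float


@dataclass
class SimulationSpec:
    """Parameters of the two-view generator.

    Defaults are desk-scale: n=120 samples, p=500 wide-view and q=30
    narrow-view features, one planted effect with 10 of 500 and 5 of 30
    active features, strength 4 against unit noise. Strengths must be
    strictly decreasing so effects are rankable by explained covariance.
    """

    n: int = 120
    p: int = 500
    q: int = 30
    n_effects: int = 1
    support_x: int | tuple[int, ...] = 10
    support_y: int | tuple[int, ...] = 5
    strengths: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    binary_y: bool = False
    overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.p < 1 or self.q < 1:
            raise ValueError("need n >= 2, p >= 1, q >= 1")
        if self.n_effects < 0:
            raise ValueError("n_effects must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        H = self.n_effects
        self.support_x = self._per_effect(self.support_x, H, "support_x")
        self.support_y = self._per_effect(self.support_y, H, "support_y")
        if any(s < 1 or s > self.p for s in self.support_x):
            raise ValueError("support_x sizes must lie in [1, p]")
        if any(s < 1 or s > self.q for s in self.support_y):
            raise ValueError("support_y sizes must lie in [1, q]")
        if not self.overlap:
            if sum(self.support_x) > self.p or sum(self.support_y) > self.q:
                raise ValueError("disjoint supports do not fit into the feature axes")
        if self.strengths is None:
            # geometric decay keeps successive effects rankable
            self.strengths = tuple(4.0 * 0.6**h for h in range(H))
        else:
            self.strengths = tuple(float(a) for a in self.strengths)
        if len(self.strengths) != H:
            raise ValueError("strengths must have one entry per effect")
        if any(a <= 0 for a in self.strengths):
            raise ValueError("strengths must be positive")
        if any(a <= b for a, b in zip(self.strengths, self.strengths[1:])):
            raise ValueError("strengths must be strictly decreasing")

    @staticmethod
    def _per_effect(value, H: int, name: str) -> tuple[int, ...]:
        if isinstance(value, (int, np.integer)):
            return tuple(int(value) for _ in range(H))
        value = tuple(int(v) for v in value)
        if len(value) != H:
            raise ValueError(f"{name} must be an int or a tuple with one entry per effect")
        return value


def _sparse_unit_vector(dim: int, support: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = np.zeros(dim)
    mags = rng.uniform(0.8, 1.2, size=support.size)  # bounded away from zero
    signs = rng.choice((-1.0, 1.0), size=support.size)
    w[support] = mags * signs
    return w / np.linalg.norm(w)


def _draw_supports(
    dim: int, sizes: tuple[int, ...], overlap: bool, rng: np.random.Generator
) -> list[np.ndarray]:
    if overlap:
        return [rng.choice(dim, size=s, replace=False) for s in sizes]
    perm = rng.permutation(dim)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(perm[start : start + s]))
        start += s
    return out


def simulate(spec: SimulationSpec) -> tuple[TwoViewDataset, list[EffectTruth]]:
    """Generate a two-view dataset plus the ground-truth effects."""
    rng = np.random.default_rng(spec.seed)
    H = spec.n_effects
    sup_x = _draw_supports(spec.p, spec.support_x, spec.overlap, rng)
    sup_y = _draw_supports(spec.q, spec.support_y, spec.overlap, rng)
    truths: list[EffectTruth] = []
    X = np.zeros((spec.n, spec.p))
    Y = np.zeros((spec.n, spec.q))
    for h in range(H):
        u = _sparse_unit_vector(spec.p, sup_x[h], rng)
        v = _sparse_unit_vector(spec.q, sup_y[h], rng)
        t = rng.standard_normal(spec.n)
        a = spec.strengths[h]
        X += a * np.outer(t, u)
        Y += a * np.outer(t, v)
        truths.append(EffectTruth(u=u, v=v, strength=a))
    if spec.noise_sd > 0:
        X += spec.noise_sd * rng.standard_normal((spec.n, spec.p))
        Y += spec.noise_sd * rng.standard_normal((spec.n, spec.q))
    if spec.binary_y:
        Y = (Y > np.median(Y, axis=0)).astype(float) + 1.0  # {1, 2} item coding
    data = TwoViewDataset(
        X=X,
        Y=Y,
        x_names=[f"vox_{j:05d}" for j in range(spec.p)],
        y_names=[f"item_{j:02d}" for j in range(spec.q)],
        sample_ids=[f"s{i:04d}" for i in range(spec.n)],
    )
    return data, truths


def support_f1(true_vec: np.ndarray, est_vec: np.ndarray) -> float:
    """F1 score of the estimated nonzero support against the true support."""
    true_set = set(np.flatnonzero(np.asarray(true_vec)).tolist())
    est_set = set(np.flatnonzero(np.asarray(est_vec)).tolist())
    if not true_set and not est_set:
        return 1.0
    tp = len(true_set & est_set)
    denom = len(true_set) + len(est_set)
    return 2.0 * tp / denom if denom else 0.0
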