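"""Dietary niche metrics: Pianka overlap, Levins breadth, cluster-bootstrap
confidence intervals, and a permutation test for breadth differences."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .composition import DietProfile, rfo_profile
from .records import ScatDataset, occurrence_counts

__all__ = [
    "OverlapResult",
    "NicheBreadthResult",
    "BreadthDifferenceTest",
    "pianka_overlap",
    "levins_breadth",
    "bootstrap_breadth_ci",
    "breadth_difference_test",
]


@dataclass(frozen=True)
class OverlapResult:
    value: float
    basis: str
    predators: tuple[str, str]


@dataclass(frozen=True)
class NicheBreadthResult:
    predator: str
    value: float
    ci_low: float
    ci_high: float
    n_boot: int
    alpha: float
    seed: int | None


@dataclass(frozen=True)
class BreadthDifferenceTest:
    predators: tuple[str, str]
    observed_diff: float
    p_value: float
    n_perm: int
    seed: int | None


def pianka_overlap(p: DietProfile, q: DietProfile) -> OverlapResult:
    """Symmetric dietary overlap Σpᵢqᵢ / √(Σpᵢ²·Σqᵢ²) on the union prey set.

    0 means disjoint diets, 1 identical; equals the cosine similarity of the
    two proportion vectors. Species absent from one profile count as zero.
    """
    if p.basis != q.basis:
        raise ValueError(
            f"profiles have different bases: {p.basis!r} vs {q.basis!r}"
        )
    prey = sorted(set(p.proportions) | set(q.proportions))
    pv, qv = p.vector(prey), q.vector(prey)
    denom = np.sqrt((pv @ pv) * (qv @ qv))
    if denom == 0:
        raise ValueError("a profile is all-zero")
    return OverlapResult(float(pv @ qv / denom), p.basis, (p.predator, q.predator))


def _levins(p: np.ndarray) -> float:
    s = float(np.sum(np.square(p)))
    if s <= 0:
        raise ValueError("profile is all-zero")
    return 1.0 / s


def levins_breadth(profile: DietProfile, standardized: bool = False) -> float:
    """Niche breadth B = 1/Σpᵢ², ranging from 1 (specialist) to k (uniform).

    With ``standardized=True`` returns (B−1)/(k−1), scaled to [0, 1].
    """
    p = np.array(list(profile.proportions.values()))
    b = _levins(p)
    if standardized:
        k = len(p)
        if k < 2:
            raise ValueError("standardized breadth needs >= 2 prey categories")
        return (b - 1.0) / (k - 1.0)
    return b


def _presence_matrix(dataset: ScatDataset, predator: str):
    recs = dataset.records_for(predator)
    prey = sorted(set().union(*(r.prey_items for r in recs)))
    idx = {p: j for j, p in enumerate(prey)}
    mat = np.zeros((len(recs), len(prey)), dtype=np.float64)
    for i, rec in enumerate(recs):
        for p in rec.prey_items:
            mat[i, idx[p]] = 1.0
    return mat, prey


def _levins_from_counts(counts: np.ndarray) -> np.ndarray:
    # counts: (..., k); returns Levins breadth along the last axis
    totals = counts.sum(axis=-1, keepdims=True)
    props = counts / totals
    return 1.0 / np.square(props).sum(axis=-1)


def bootstrap_breadth_ci(
    dataset: ScatDataset,
    predator: str,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> NicheBreadthResult:
    """Percentile bootstrap CI for Levins breadth, resampling whole scats.

    The scat is the independent sampling unit (occurrences within a scat are
    not), so entire scats are drawn with replacement; each replicate
    recomputes the RFO profile and its breadth.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    mat, _ = _presence_matrix(dataset, predator)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need >= 2 scats to bootstrap")
    point = _levins_from_counts(mat.sum(axis=0))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_counts = mat[idx].sum(axis=1)  # (n_boot, k); rows never all-zero
    boots = _levins_from_counts(boot_counts)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return NicheBreadthResult(
        predator=predator,
        value=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
    )


def breadth_difference_test(
    dataset: ScatDataset,
    pred_a: str,
    pred_b: str,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> BreadthDifferenceTest:
    """Permutation test for |B_a − B_b| on RFO profiles.

    The null pools all scats and randomly reassigns predator labels
    preserving group sizes; p = (1 + #{null ≥ observed}) / (n_perm + 1),
    two-sided by the absolute-value statistic.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    profile_a = rfo_profile(occurrence_counts(dataset, pred_a))
    profile_b = rfo_profile(occurrence_counts(dataset, pred_b))
    observed = abs(levins_breadth(profile_a) - levins_breadth(profile_b))

    mat_a, prey_a = _presence_matrix(dataset, pred_a)
    mat_b, prey_b = _presence_matrix(dataset, pred_b)
    prey = sorted(set(prey_a) | set(prey_b))
    if len(prey) < 2:
        warnings.warn(
            "pooled dataset has a single prey species; breadth difference "
            "is degenerate (p = 1)",
            stacklevel=2,
        )
        return BreadthDifferenceTest(
            (pred_a, pred_b), observed, 1.0, n_perm, seed
        )

    def _expand(mat, names):
        full = np.zeros((mat.shape[0], len(prey)))
        cols = [prey.index(p) for p in names]
        full[:, cols] = mat
        return full

    pooled = np.vstack([_expand(mat_a, prey_a), _expand(mat_b, prey_b)])
    n_a, n_total = mat_a.shape[0], pooled.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_total)
        ca = pooled[perm[:n_a]].sum(axis=0)
        cb = pooled[perm[n_a:]].sum(axis=0)
        null[i] = abs(_levins_from_counts(ca) - _levins_from_counts(cb))
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    return BreadthDifferenceTest((pred_a, pred_b), observed, float(p), n_perm, seed)
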