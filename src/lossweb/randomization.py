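"""Null-model manipulations of community matrices and random-matrix ensembles.

Three randomisations destroy empirical patterning at different depths
while preserving topology, the diagonal and the multiset of non-zero
off-diagonal values:

* **full** — permute all non-zero interspecific strengths over the
  non-zero positions (destroys pairwise and community structure);
* **weak** — keep reciprocal value pairs intact but move them to random
  position-pairs with random orientation (2-link loops preserved,
  community asymmetry destroyed);
* **minimal** — like weak, but each pair keeps its above/below-diagonal
  orientation (community asymmetry preserved too).

Two restorations rebuild hierarchy in a randomised matrix:

* **restore_pairwise_asymmetry** — re-pair the sorted values strongest
  with weakest (minimising 2-link loop weights), placed randomly;
* **restore_community_asymmetry** — additionally flip every pair so its
  stronger member sits below the diagonal.

`random_competition_matrix` builds May-style random interference
matrices (all links -|Normal(0, sigma)|, diagonal -1) with independent,
asymmetric (strongest-with-weakest) or symmetric (adjacent-in-order)
pairing of the drawn values, and `stability_threshold_curve` scans the
(S, C) plane for the connectance at which an ensemble stops being
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy_loss import NormalizedMatrix, as_matrix
from .stability import dominant_eigenvalue

__all__ = [
    "ManipulationResult",
    "RandomMatrixSpec",
    "MANIPULATIONS",
    "full_randomize",
    "weak_randomize",
    "minimal_randomize",
    "restore_pairwise_asymmetry",
    "restore_community_asymmetry",
    "random_competition_matrix",
    "stable_fraction",
    "stability_threshold_curve",
]


def _wrap_like(template, arr: np.ndarray):
    if isinstance(template, NormalizedMatrix):
        return NormalizedMatrix(list(template.species), arr)
    return arr


def _offdiag_mask(a: np.ndarray) -> np.ndarray:
    mask = a != 0
    np.fill_diagonal(mask, False)
    return mask


def _reciprocal_pairs(a: np.ndarray) -> list[tuple[int, int]]:
    """Unordered position-pairs with both links non-zero; raise on one-sided links."""
    s = a.shape[0]
    pairs = []
    for i in range(s):
        for j in range(i + 1, s):
            if (a[i, j] != 0) != (a[j, i] != 0):
                raise ValueError(
                    f"one-sided non-zero link between positions {i} and {j}: "
                    "pair manipulations need a reciprocal topology"
                )
            if a[i, j] != 0:
                pairs.append((i, j))
    return pairs


def full_randomize(n, rng: np.random.Generator):
    """Permute all non-zero off-diagonal values over the non-zero positions."""
    a = as_matrix(n).copy()
    mask = _offdiag_mask(a)
    vals = a[mask]
    a[mask] = rng.permutation(vals)
    return _wrap_like(n, a)


def _reassign_pairs(a: np.ndarray, rng: np.random.Generator, keep_orientation: bool) -> np.ndarray:
    pairs = _reciprocal_pairs(a)
    # value pair at position-pair (i, j), i < j: (above, below) = (a[i,j], a[j,i])
    value_pairs = [(a[i, j], a[j, i]) for i, j in pairs]
    out = a.copy()
    order = rng.permutation(len(pairs))
    for pos_idx, val_idx in enumerate(order):
        i, j = pairs[pos_idx]
        above, below = value_pairs[val_idx]
        if not keep_orientation and rng.random() < 0.5:
            above, below = below, above
        out[i, j] = above
        out[j, i] = below
    return out


def weak_randomize(n, rng: np.random.Generator):
    """Move reciprocal value pairs to random position-pairs, random orientation."""
    return _wrap_like(n, _reassign_pairs(as_matrix(n), rng, keep_orientation=False))


def minimal_randomize(n, rng: np.random.Generator):
    """Like weak randomisation but each pair keeps its above/below orientation."""
    return _wrap_like(n, _reassign_pairs(as_matrix(n), rng, keep_orientation=True))


def _strong_weak_pairs(vals: np.ndarray) -> list[tuple[float, float]]:
    """Pair sorted magnitudes strongest-with-weakest (stable on ties)."""
    order = np.argsort(-np.abs(vals), kind="stable")
    v = vals[order]
    m = len(v) // 2
    return [(v[k], v[len(v) - 1 - k]) for k in range(m)]


def restore_pairwise_asymmetry(n, rng: np.random.Generator):
    """Re-pair the value multiset strongest-with-weakest and place randomly.

    This minimises every 2-link loop weight achievable with the given
    values; strong links can land on either side of the diagonal.
    """
    a = as_matrix(n).copy()
    pairs = _reciprocal_pairs(a)
    mask = _offdiag_mask(a)
    vals = a[mask]
    if len(vals) % 2:
        raise ValueError("odd number of non-zero off-diagonal values; cannot form pairs")
    value_pairs = _strong_weak_pairs(vals)
    order = rng.permutation(len(pairs))
    for pos_idx, val_idx in enumerate(order):
        i, j = pairs[pos_idx]
        strong, weak = value_pairs[val_idx]
        if rng.random() < 0.5:
            strong, weak = weak, strong
        a[i, j] = strong
        a[j, i] = weak
    return _wrap_like(n, a)


def restore_community_asymmetry(n):
    """Flip each reciprocal pair so its stronger member lies below the diagonal."""
    a = as_matrix(n).copy()
    for i, j in _reciprocal_pairs(a):
        if abs(a[i, j]) > abs(a[j, i]):
            a[i, j], a[j, i] = a[j, i], a[i, j]
    return _wrap_like(n, a)


MANIPULATIONS = {
    "full": full_randomize,
    "weak": weak_randomize,
    "minimal": minimal_randomize,
    "restore_pairwise": restore_pairwise_asymmetry,
    "restore_community": lambda n, rng: restore_community_asymmetry(
        restore_pairwise_asymmetry(n, rng)
    ),
}


@dataclass(frozen=True)
class RandomMatrixSpec:
    """Parameters of a May-style random interference-competition matrix.

    Unordered species pairs are activated independently with probability
    ``C`` (expected connectance); every link is the negative magnitude of
    a Normal(0, sigma) draw; ``pairing`` controls how drawn values are
    coupled into reciprocal pairs.
    """

    S: int
    C: float
    sigma: float = 0.8
    pairing: str = "independent"  # independent | asymmetric | symmetric
    diagonal: float = -1.0
    reps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.C <= 1):
            raise ValueError("connectance C must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.pairing not in ("independent", "asymmetric", "symmetric"):
            raise ValueError(f"unknown pairing {self.pairing!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.S < 2:
            raise ValueError("need at least 2 species")


def random_competition_matrix(spec: RandomMatrixSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one random competition matrix according to ``spec``."""
    s = spec.S
    a = np.zeros((s, s))
    np.fill_diagonal(a, spec.diagonal)
    candidates = [(i, j) for i in range(s) for j in range(i + 1, s)]
    active = [p for p in candidates if rng.random() < spec.C]
    n = len(active)
    if n == 0:
        return a
    if spec.pairing == "independent":
        for i, j in active:
            a[i, j] = -abs(rng.normal(0.0, spec.sigma))
            a[j, i] = -abs(rng.normal(0.0, spec.sigma))
        return a
    vals = -np.abs(rng.normal(0.0, spec.sigma, size=2 * n))
    v = vals[np.argsort(-np.abs(vals), kind="stable")]  # strongest first
    if spec.pairing == "asymmetric":
        value_pairs = [(v[k], v[2 * n - 1 - k]) for k in range(n)]
    else:  # symmetric: adjacent in sorted order
        value_pairs = [(v[2 * k], v[2 * k + 1]) for k in range(n)]
    order = rng.permutation(n)
    for pos_idx, val_idx in enumerate(order):
        i, j = active[pos_idx]
        first, second = value_pairs[val_idx]
        if rng.random() < 0.5:
            first, second = second, first
        a[i, j] = first
        a[j, i] = second
    return a


def stable_fraction(spec: RandomMatrixSpec, rng: np.random.Generator) -> float:
    """Fraction of ``spec.reps`` random matrices with Re(lambda_d) < 0."""
    n_stable = sum(
        dominant_eigenvalue(random_competition_matrix(spec, rng)) < 0 for _ in range(spec.reps)
    )
    return n_stable / spec.reps


def stability_threshold_curve(
    s_values,
    c_values,
    reps: int = 100,
    stable_fraction_cutoff: float = 0.05,
    pairing: str = "independent",
    sigma: float = 0.8,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Largest connectance per richness at which an ensemble stays 'stable enough'.

    For each S, reports the largest C whose ensemble stable fraction is
    >= ``stable_fraction_cutoff`` (NaN when even the smallest C falls
    below).  Returns (threshold table, full per-cell stable-fraction grid).
    """
    s_values = list(s_values)
    c_values = sorted(c_values)
    if not s_values or not c_values:
        raise ValueError("empty S or C grid")
    if reps < 20:
        raise ValueError("need at least 20 replicates per cell")
    if not (0 < stable_fraction_cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    grid_rows = []
    thresh_rows = []
    for s in s_values:
        threshold = np.nan
        for c in c_values:
            spec = RandomMatrixSpec(S=s, C=c, sigma=sigma, pairing=pairing, reps=reps)
            frac = stable_fraction(spec, rng)
            grid_rows.append({"S": s, "C": c, "stable_fraction": frac})
            if frac >= stable_fraction_cutoff:
                threshold = c
        thresh_rows.append({"S": s, "C_threshold": threshold})
    return pd.DataFrame(thresh_rows), pd.DataFrame(grid_rows)


@dataclass
class ManipulationResult:
    """Ensemble of manipulated matrices with per-matrix stability metrics."""

    kind: str
    matrices: list = field(default_factory=list)
    metrics: pd.DataFrame | None = None
    seed: int | None = None
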