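"""Hierarchy and asymmetry metrics for competition matrices.

Steep competitive hierarchies leave two signatures in a community matrix.
Within a reciprocal pair of interaction strengths, one direction ("top
down", the effect of the dominant on the subordinate) is much stronger
than the other — *pairwise asymmetry*, the mean stronger/weaker magnitude
ratio over pairs.  Across the whole matrix, ordering species by rank puts
the strong values below the diagonal — *community asymmetry*, the ratio
of mean below- to mean above-diagonal magnitude maximised over all
species orderings.  Both indices are computed on magnitudes of the
(non-positive) entries and are invariant to a positive rescaling of the
matrix.

Contest outcomes themselves yield the win index: the mean, over species
pairs with at least one decisive contest, of the dominant competitor's
share of decisive wins — 0.5 for balanced outcomes, 1 for complete
polarisation.  A triad-census intransitivity score based on the dominance
digraph (|a_ij| > |a_ji|) distinguishes linear hierarchies (-1) from
rock-paper-scissors structures (+1); it is an operational variant, not a
reproduction of any published intransitivity index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np

from .contact_io import ContactData
from .energy_loss import as_matrix

__all__ = [
    "PairwiseAsymmetry",
    "CommunityAsymmetry",
    "WinIndex",
    "pairwise_asymmetry",
    "community_asymmetry",
    "community_asymmetry_at_order",
    "win_index",
    "intransitivity_index",
]

EXACT_ORDER_LIMIT = 9


class PairwiseAsymmetry(NamedTuple):
    value: float
    n_pairs: int
    n_excluded: int


class WinIndex(NamedTuple):
    value: float
    n_pairs: int
    n_excluded: int


@dataclass
class CommunityAsymmetry:
    value: float
    best_order: tuple[int, ...]
    method: str  # "exact" | "heuristic"


def _magnitudes(m) -> np.ndarray:
    a = as_matrix(m)
    if (np.where(~np.eye(a.shape[0], dtype=bool), a, 0) > 0).any():
        raise ValueError("competition matrices must have non-positive off-diagonal entries")
    return np.abs(a)


def pairwise_asymmetry(m) -> PairwiseAsymmetry:
    """Mean stronger/weaker magnitude ratio over reciprocal pairs (>= 1).

    Pairs with a zero member (one-sided links) are excluded and tallied in
    ``n_excluded``.
    """
    mag = _magnitudes(m)
    s = mag.shape[0]
    ratios = []
    excluded = 0
    for i in range(s):
        for j in range(i + 1, s):
            x, y = mag[i, j], mag[j, i]
            if x > 0 and y > 0:
                ratios.append(max(x, y) / min(x, y))
            elif x > 0 or y > 0:
                excluded += 1
    if not ratios:
        raise ValueError("no reciprocal pair of non-zero interaction strengths")
    return PairwiseAsymmetry(float(np.mean(ratios)), len(ratios), excluded)


def _pair_arrays(mag: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    s = mag.shape[0]
    ii, jj = np.triu_indices(s, k=1)
    x = mag[ii, jj]  # sits above the diagonal when i precedes j
    y = mag[jj, ii]
    keep = (x > 0) | (y > 0)
    return ii[keep], jj[keep], x[keep], y[keep]


def community_asymmetry_at_order(m, order=None) -> float:
    """Below/above mean-magnitude ratio at one fixed species ordering.

    ``order`` lists species indices from top to bottom of the hierarchy;
    default is the stored order.  Only non-zero entries enter the means.
    """
    mag = _magnitudes(m)
    s = mag.shape[0]
    if order is None:
        order = np.arange(s)
    perm = mag[np.ix_(order, order)]
    tri = np.tril(perm, k=-1)
    below = tri[tri > 0]
    triu = np.triu(perm, k=1)
    above = triu[triu > 0]
    if below.size == 0 or above.size == 0:
        raise ValueError("need non-zero entries on both sides of the diagonal")
    return float(below.mean() / above.mean())


@lru_cache(maxsize=4)
def _all_permutations(s: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(s))), dtype=np.int8)


def _perm_batches(s: int, chunk: int = 50000):
    """Yield all S! orderings in array batches; cached whole for small S."""
    if s <= 9:
        perms = _all_permutations(s)
        for start in range(0, len(perms), chunk):
            yield perms[start : start + chunk]
        return
    it = itertools.permutations(range(s))
    while True:
        batch = list(itertools.islice(it, chunk))
        if not batch:
            return
        yield np.array(batch, dtype=np.int8)


def _ratio_over_orders(mag: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Vectorised below/above ratio for a batch of orderings."""
    ii, jj, x, y = _pair_arrays(mag)
    pos = np.argsort(orders, axis=1)  # pos[p, species] = rank in ordering p
    # species ii precedes jj  =>  entry x = mag[ii, jj] lands above the diagonal
    ii_first = pos[:, ii] < pos[:, jj]
    above_vals = np.where(ii_first, x, y)
    below_vals = np.where(ii_first, y, x)
    above_sum = above_vals.sum(axis=1)
    below_sum = below_vals.sum(axis=1)
    above_cnt = (above_vals > 0).sum(axis=1)
    below_cnt = (below_vals > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (below_sum / below_cnt) / (above_sum / above_cnt)
    ratio[above_cnt == 0] = np.inf
    ratio[below_cnt == 0] = 0.0
    return ratio


def _dominance_order(mag: np.ndarray) -> np.ndarray:
    """Initial guess: rank species by net inflicted minus suffered losses."""
    score = mag.sum(axis=0) - mag.sum(axis=1)
    return np.argsort(-score, kind="stable")


def community_asymmetry(
    m,
    exact_limit: int = EXACT_ORDER_LIMIT,
    n_restarts: int = 50,
    rng: np.random.Generator | None = None,
) -> CommunityAsymmetry:
    """Maximise the below/above ratio over species orderings.

    Exhaustive over all S! orderings for S <= ``exact_limit`` (vectorised
    in permutation batches); beyond that a steepest-ascent hill-climb over
    pairwise transpositions from ``n_restarts`` starts (the dominance-rank
    order plus random orders) reports a flagged lower bound.
    """
    mag = _magnitudes(m)
    s = mag.shape[0]
    ii, jj, x, y = _pair_arrays(mag)
    if not ((x > 0) & (y > 0)).any():
        raise ValueError("no reciprocal pair of non-zero interaction strengths")

    if s <= exact_limit:
        best_val, best_order = -np.inf, None
        for batch in _perm_batches(s):
            ratios = _ratio_over_orders(mag, batch)
            k = int(np.argmax(ratios))
            if ratios[k] > best_val:
                best_val = float(ratios[k])
                best_order = tuple(int(v) for v in batch[k])
        return CommunityAsymmetry(best_val, best_order, "exact")

    if rng is None:
        rng = np.random.default_rng()
    starts = [_dominance_order(mag)]
    starts += [rng.permutation(s) for _ in range(max(0, n_restarts - 1))]
    best_val, best_order = -np.inf, None
    swaps = list(itertools.combinations(range(s), 2))
    for order in starts:
        order = np.asarray(order)
        val = _ratio_over_orders(mag, order[np.newaxis, :])[0]
        improved = True
        while improved:
            improved = False
            cand = np.tile(order, (len(swaps), 1))
            for r, (p, q) in enumerate(swaps):
                cand[r, [p, q]] = cand[r, [q, p]]
            ratios = _ratio_over_orders(mag, cand)
            k = int(np.argmax(ratios))
            if ratios[k] > val + 1e-15:
                val = float(ratios[k])
                order = cand[k]
                improved = True
        if val > best_val:
            best_val, best_order = val, tuple(int(v) for v in order)
    return CommunityAsymmetry(best_val, best_order, "heuristic")


def win_index(contacts: ContactData) -> WinIndex:
    """Mean dominant win share over pairs with decisive contests (in [0.5, 1]).

    For each interspecific pair with W_ij + W_ji > 0 the contribution is
    max(W_ij, W_ji) / (W_ij + W_ji); draws never enter the denominator.
    Interacting pairs whose contests were all draws are excluded and
    tallied.
    """
    w = contacts.wins
    s = contacts.n_species
    shares = []
    excluded = 0
    for i in range(s):
        for j in range(i + 1, s):
            decisive = w[i, j] + w[j, i]
            if decisive > 0:
                shares.append(max(w[i, j], w[j, i]) / decisive)
            elif contacts.draws[i, j] > 0:
                excluded += 1
    if not shares:
        raise ValueError("no decisive contests in the assemblage")
    return WinIndex(float(np.mean(shares)), len(shares), excluded)


def intransitivity_index(m) -> float | None:
    """Triad-census intransitivity of the dominance digraph (operational variant).

    Species j dominates i when |a_ij| > |a_ji| (j inflicts the larger
    loss).  Among triads whose three dyads all have a defined dominance
    direction, the score is 1 - 2 * (fraction of transitive triads):
    -1 for a perfect linear hierarchy, +1 for pure rock-paper-scissors.
    Returns None when no complete triad exists (e.g. S < 3).
    """
    mag = _magnitudes(m)
    s = mag.shape[0]
    if s < 3:
        return None
    # beats[j, i] True when j dominates i
    beats = (mag.T > mag) & ((mag > 0) | (mag.T > 0))
    n_complete = 0
    n_transitive = 0
    for i, j, k in itertools.combinations(range(s), 3):
        dyads = [(i, j), (i, k), (j, k)]
        if not all(beats[a, b] or beats[b, a] for a, b in dyads):
            continue
        n_complete += 1
        outdeg = {v: 0 for v in (i, j, k)}
        for a, b in dyads:
            if beats[a, b]:
                outdeg[a] += 1
            else:
                outdeg[b] += 1
        # a complete 3-tournament is transitive iff out-degrees are {2,1,0}
        if sorted(outdeg.values()) == [0, 1, 2]:
            n_transitive += 1
    if n_complete == 0:
        return None
    return float(1.0 - 2.0 * (n_transitive / n_complete))
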