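"""Feedback-loop weights.

The weight of a directed feedback loop of length k through species
i1 -> i2 -> ... -> ik -> i1 is the geometric mean of its link magnitudes
scaled by the self-regulation terms of its members:

    w^(k) = | a_{i1 i2} a_{i2 i3} ... a_{ik i1} / (a_{i1 i1} ... a_{ik ik}) |^(1/k)

In interference-competition networks every link is negative, so loops of
even length are positive (self-reinforcing, destabilising) and loops of
odd length negative (self-dampening).  The heaviest 2-link loop,
w^(2)_max, is Chesson's niche overlap in the 2-species case and tracks
the critical self-regulation of larger systems closely.

Loop weight depends only on the row-normalised matrix (each link divided
by the self-regulation term of its row), so the spectrum is invariant
under normalisation.  The per-length maximum is found by an exact dynamic
programme over vertex subsets in log-magnitude space; a brute-force
enumerator built on :func:`networkx.simple_cycles` serves as an
independent oracle for small systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .energy_loss import as_matrix

__all__ = [
    "LoopWeightSpectrum",
    "loop_weight",
    "max_two_link_loop_weight",
    "max_loop_weight_per_length",
    "max_loop_weight_brute",
]

EXACT_SIZE_LIMIT = 20


@dataclass
class LoopWeightSpectrum:
    """Maximum loop weight per length with the cycles attaining them.

    ``entries`` maps loop length k to a dict with keys ``max_weight``,
    ``sign`` (+1 for even k, -1 for odd k: all links negative), ``cycle``
    (member indices in traversal order) and ``method`` ('exact' or
    'sampled'; sampled maxima are lower bounds).
    """

    n_species: int
    entries: dict[int, dict] = field(default_factory=dict)

    @property
    def lengths(self) -> list[int]:
        return sorted(self.entries)

    def max_weight(self, k: int) -> float:
        return self.entries[k]["max_weight"]

    def to_frame(self, species: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for k in self.lengths:
            e = self.entries[k]
            cyc = e["cycle"]
            labels = [species[i] for i in cyc] if species is not None else [str(i) for i in cyc]
            rows.append(
                {
                    "k": k,
                    "max_weight": e["max_weight"],
                    "sign": e["sign"],
                    "argmax_cycle": ";".join(labels),
                    "method": e["method"],
                }
            )
        return pd.DataFrame(rows, columns=["k", "max_weight", "sign", "argmax_cycle", "method"])


def _log_weights(m) -> np.ndarray:
    """Log-magnitudes of the row-normalised matrix; -inf marks absent links."""
    a = as_matrix(m)
    d = a.diagonal()
    if (d >= 0).any():
        raise ValueError("loop weights require a strictly negative diagonal")
    abar = np.abs(a) / np.abs(d)[:, np.newaxis]
    with np.errstate(divide="ignore"):
        logw = np.log(abar)
    np.fill_diagonal(logw, -np.inf)
    return logw


def loop_weight(m, cycle) -> float:
    """Weight of one feedback loop given as a sequence of >= 2 distinct members.

    ``cycle`` holds species indices (or labels if ``m`` carries a species
    list); the closing link back to the first member is implicit.
    """
    a = as_matrix(m)
    species = getattr(m, "species", None)
    idx = [species.index(c) if isinstance(c, str) and species else int(c) for c in cycle]
    k = len(idx)
    if k < 2:
        raise ValueError("a feedback loop needs at least 2 members")
    if len(set(idx)) != k:
        raise ValueError("loop members must be distinct (simple cycle)")
    logw = _log_weights(a)
    total = 0.0
    for t in range(k):
        step = logw[idx[t], idx[(t + 1) % k]]
        if step == -np.inf:
            raise ValueError(f"link {idx[t]} -> {idx[(t + 1) % k]} is absent (zero strength)")
        total += step
    return float(np.exp(total / k))


def max_two_link_loop_weight(m) -> float:
    """Heaviest 2-link loop: max over reciprocal pairs of sqrt(a_ij a_ji / |a_ii a_jj|)."""
    a = as_matrix(m)
    d = np.abs(a.diagonal())
    if (a.diagonal() >= 0).any():
        raise ValueError("requires a strictly negative diagonal")
    prod = (a * a.T) / np.outer(d, d)
    np.fill_diagonal(prod, 0.0)
    reciprocal = (a != 0) & (a.T != 0)
    np.fill_diagonal(reciprocal, False)
    if not reciprocal.any():
        return 0.0
    return float(np.sqrt(prod[reciprocal].max()))


def max_loop_weight_per_length(
    m,
    k_max: int | None = None,
    *,
    exact_limit: int = EXACT_SIZE_LIMIT,
    rng: np.random.Generator | None = None,
    n_samples: int = 20000,
) -> LoopWeightSpectrum:
    """Maximum loop weight for every length k = 2..min(S, k_max).

    Exact for S <= ``exact_limit`` via a dynamic programme over vertex
    subsets: paths are anchored at their lowest-index member, extended one
    vertex at a time while accumulating log link magnitudes, and closed
    against the anchor.  Lengths with no simple cycle are absent from the
    spectrum.  Above the limit a uniform random-cycle sampler provides
    flagged lower bounds.
    """
    logw = _log_weights(m)
    s = logw.shape[0]
    if k_max is None:
        k_max = s
    k_max = min(k_max, s)
    if s > exact_limit:
        return _sampled_spectrum(logw, k_max, rng, n_samples)

    spectrum = LoopWeightSpectrum(s)
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    for anchor in range(s):
        # states: (mask of visited vertices incl. anchor, last vertex) -> best log-sum;
        # only vertices > anchor may join, so each cycle is found once, at its
        # lowest-index member, in its direction of traversal.
        states: dict[tuple[int, int], float] = {(1 << anchor, anchor): 0.0}
        parents: dict[tuple[int, int], int | None] = {(1 << anchor, anchor): None}
        for length in range(1, k_max):
            new_states: dict[tuple[int, int], float] = {}
            for (mask, last), val in states.items():
                for nxt in range(anchor + 1, s):
                    if mask & (1 << nxt):
                        continue
                    step = logw[last, nxt]
                    if step == -np.inf:
                        continue
                    key = (mask | (1 << nxt), nxt)
                    cand = val + step
                    if cand > new_states.get(key, -np.inf):
                        new_states[key] = cand
                        parents[key] = last
            states = new_states
            k = length + 1
            for (mask, last), val in states.items():
                close = logw[last, anchor]
                if close == -np.inf:
                    continue
                total = val + close
                if total > best.get(k, (-np.inf, ()))[0]:
                    cyc = [last]
                    node, msk = last, mask
                    while True:
                        prev = parents[(msk, node)]
                        if prev is None:
                            break
                        msk &= ~(1 << node)
                        node = prev
                        cyc.append(node)
                    best[k] = (total, tuple(reversed(cyc)))
            if not states:
                break
    for k, (logsum, cyc) in best.items():
        spectrum.entries[k] = {
            "max_weight": float(np.exp(logsum / k)),
            "sign": 1 if k % 2 == 0 else -1,
            "cycle": list(cyc),
            "method": "exact",
        }
    return spectrum


def _sampled_spectrum(
    logw: np.ndarray, k_max: int, rng: np.random.Generator | None, n_samples: int
) -> LoopWeightSpectrum:
    """Random simple-cycle sampling: flagged lower bounds on the maxima."""
    if rng is None:
        rng = np.random.default_rng()
    s = logw.shape[0]
    spectrum = LoopWeightSpectrum(s)
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    for _ in range(n_samples):
        k = int(rng.integers(2, k_max + 1))
        members = rng.permutation(s)[:k]
        anchor_pos = int(np.argmin(members))
        members = np.roll(members, -anchor_pos)
        total = 0.0
        ok = True
        for t in range(k):
            step = logw[members[t], members[(t + 1) % k]]
            if step == -np.inf:
                ok = False
                break
            total += step
        if ok and total > best.get(k, (-np.inf, ()))[0]:
            best[k] = (total, tuple(int(v) for v in members))
    for k, (logsum, cyc) in best.items():
        spectrum.entries[k] = {
            "max_weight": float(np.exp(logsum / k)),
            "sign": 1 if k % 2 == 0 else -1,
            "cycle": list(cyc),
            "method": "sampled",
        }
    return spectrum


def max_loop_weight_brute(m, k_max: int | None = None) -> LoopWeightSpectrum:
    """Independent oracle: enumerate every simple directed cycle via networkx.

    Exponential in S; intended for cross-checks on small matrices.
    """
    logw = _log_weights(m)
    s = logw.shape[0]
    if k_max is None:
        k_max = s
    g = nx.DiGraph()
    g.add_nodes_from(range(s))
    for i in range(s):
        for j in range(s):
            if i != j and logw[i, j] > -np.inf:
                g.add_edge(i, j)
    spectrum = LoopWeightSpectrum(s)
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    for cyc in nx.simple_cycles(g):
        k = len(cyc)
        if k < 2 or k > k_max:
            continue
        total = sum(logw[cyc[t], cyc[(t + 1) % k]] for t in range(k))
        if total > best.get(k, (-np.inf, ()))[0]:
            best[k] = (total, tuple(cyc))
    for k, (logsum, cyc) in best.items():
        spectrum.entries[k] = {
            "max_weight": float(np.exp(logsum / k)),
            "sign": 1 if k % 2 == 0 else -1,
            "cycle": list(cyc),
            "method": "exact",
        }
    return spectrum
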