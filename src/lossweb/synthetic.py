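"""Synthetic assemblage generator.

Emulates the contest data of sessile encrusting assemblages (5-11
species, connectance near 0.9, near-transitive dominance hierarchies,
weak competitors often the most abundant) so that every pipeline stage
is testable without field data.

Species receive distinct competitive ranks 1..S (1 = strongest).  The
probability that the higher-ranked member of a pair wins a decisive
contest follows a logistic curve in the rank difference with steepness
``beta``: beta = 0 gives coin-flip outcomes, large beta a deterministic
hierarchy.  Contest numbers scale with the geometric mean of the two
species' abundances, and intraspecific contests scale with abundance
alone, so rare species frequently have no observed self-regulation —
exercising the diagonal-fill path downstream.  Abundances are log-normal
around a trend in competitive ability whose slope ``abundance_gradient``
is negative by default: weak competitors (opportunistic colonisers)
dominate numerically while losing contests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .contact_io import ContactData

__all__ = ["SyntheticSpec", "generate_assemblage", "generate_ensemble"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    Parameters
    ----------
    S : species count (empirical range 5-11).
    beta : hierarchy steepness on the logistic rank-difference scale;
        0 = no hierarchy, ~4 = near-deterministic dominance.
    draw_prob : probability a contest ends tied.
    mean_contests : expected contests for a pair of average abundance.
    connectance_target : probability a pair interacts at all.
    abundance_gradient : slope of log-abundance versus competitive
        ability (negative = strong competitors rare, weak abundant).
    base_abundance : geometric-mean colony count per species.
    abundance_sigma : log-scale abundance noise.
    intra_rate : expected intraspecific contests per colony.
    seed : base RNG seed for reproducible ensembles.
    """

    S: int = 8
    beta: float = 1.5
    draw_prob: float = 0.2
    mean_contests: float = 20.0
    connectance_target: float = 0.9
    abundance_gradient: float = -0.25
    base_abundance: float = 20.0
    abundance_sigma: float = 0.4
    intra_rate: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("need at least 2 species")
        if not (0 <= self.draw_prob < 1):
            raise ValueError("draw_prob must be in [0, 1)")
        if self.mean_contests <= 0:
            raise ValueError("mean_contests must be positive")
        if not (0 < self.connectance_target <= 1):
            raise ValueError("connectance_target must be in (0, 1]")
        if self.beta < 0 or self.intra_rate < 0:
            raise ValueError("beta and intra_rate must be >= 0")


def generate_assemblage(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    assemblage_id: str = "synthetic",
) -> ContactData:
    """Draw one assemblage.  Species are listed in rank order (strongest first)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    s = spec.S
    species = [f"sp{k + 1:02d}" for k in range(s)]
    rank = np.arange(1, s + 1)  # 1 = strongest
    ability = (s - rank).astype(float)
    log_b = (
        np.log(spec.base_abundance)
        + spec.abundance_gradient * (ability - ability.mean())
        + rng.normal(0.0, spec.abundance_sigma, size=s)
    )
    abundance = np.maximum(1, np.round(np.exp(log_b))).astype(np.int64)

    wins = np.zeros((s, s), dtype=np.int64)
    draws = np.zeros((s, s), dtype=np.int64)
    mean_b = abundance.mean()
    for i in range(s):
        for j in range(i + 1, s):
            if rng.random() >= spec.connectance_target:
                continue
            lam = spec.mean_contests * np.sqrt(abundance[i] * abundance[j]) / mean_b
            n = rng.poisson(lam)
            if n == 0:
                continue
            d = rng.binomial(n, spec.draw_prob)
            decisive = n - d
            p_i = expit(spec.beta * (rank[j] - rank[i]))  # i stronger => p > 0.5
            w_i = rng.binomial(decisive, p_i)
            wins[i, j] = w_i
            wins[j, i] = decisive - w_i
            draws[i, j] = draws[j, i] = d
    for i in range(s):
        n_intra = rng.poisson(spec.intra_rate * abundance[i])
        ties = rng.binomial(n_intra, spec.draw_prob)
        wins[i, i] = n_intra - ties
        draws[i, i] = ties
    return ContactData(assemblage_id, species, wins, draws, abundance)


def generate_ensemble(
    spec: SyntheticSpec, n: int, seed: int | None = None
) -> list[ContactData]:
    """Generate ``n`` independent assemblages with seeds derived from (seed, index)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = spec.seed if seed is None else seed
    out = []
    for k in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(base, spawn_key=(k,)))
        out.append(generate_assemblage(spec, rng, assemblage_id=f"synthetic_{k:03d}"))
    return out
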