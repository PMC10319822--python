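"""Energy-loss webs and Jacobian (community) matrices.

Interference competition costs energy whatever the outcome.  The loss rate
of species *i* attributable to species *j* is a weighted sum of contest
outcomes,

    f_ij = p_W * W_ij + p_L * L_ij + p_D * D_ij,

with per-colony, per-time costs ``p_W`` (winning), ``p_L`` (losing) and
``p_D`` (drawing), all <= 0, and L_ij = W_ji.  Intraspecific contests
count each overgrowth event as one win plus one loss for the species, and
double the tied-outcome count because both colonies belong to it.

Assuming Lotka-Volterra dynamics at steady state and unit colony biomass,
the per-capita interaction strengths (Jacobian elements) follow as

    a_ij = f_ij / B_j,

where B_j is the colony abundance of species *j*.  Diagonal entries that
cannot be estimated (no intraspecific contests observed, common for rare
species) are filled with a small negative value proportional to the mean
Jacobian element, and flagged.

Normalisation divides each row by the magnitude of its diagonal term,
producing a community matrix with uniform diagonal -1 that preserves the
feedback structure and the critical self-regulation of the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_io import ContactData

__all__ = [
    "CostParameters",
    "DEFAULT_COSTS",
    "EnergyLossWeb",
    "JacobianMatrix",
    "NormalizedMatrix",
    "energy_loss_web",
    "jacobian",
    "normalize",
    "as_matrix",
]


@dataclass(frozen=True)
class CostParameters:
    """Energy loss per colony per unit time for each contest outcome.

    All three costs are losses and must be <= 0.  Defaults: winning is
    cheap (-0.1), losing by being overgrown is expensive (-0.9), drawing
    costs both colonies a little (-0.2).
    """

    p_win: float = -0.1
    p_loss: float = -0.9
    p_draw: float = -0.2

    def __post_init__(self) -> None:
        for name in ("p_win", "p_loss", "p_draw"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0 (an energy loss), got {getattr(self, name)}")


DEFAULT_COSTS = CostParameters()


@dataclass
class EnergyLossWeb:
    """Matrix of loss rates f_ij (biomass/time, <= 0) and the costs used."""

    species: list[str]
    f: np.ndarray
    costs: CostParameters

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if (self.f > 0).any():
            raise ValueError("loss rates must be <= 0 everywhere")


@dataclass
class JacobianMatrix:
    """Per-capita interaction strengths a_ij (1/time, <= 0).

    ``diag_estimated[i]`` is True where a_ii was filled from the mean
    Jacobian element rather than observed from intraspecific contests.
    """

    species: list[str]
    a: np.ndarray
    diag_estimated: np.ndarray = field(default=None)  # type: ignore[assignment]
    diag_fill_factor: float | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.diag_estimated is None:
            self.diag_estimated = np.zeros(self.a.shape[0], dtype=bool)
        self.diag_estimated = np.asarray(self.diag_estimated, dtype=bool)
        if (self.a > 0).any():
            raise ValueError("interaction strengths must be <= 0 everywhere")


@dataclass
class NormalizedMatrix:
    """Row-normalised community matrix with uniform diagonal -1."""

    species: list[str]
    abar: np.ndarray

    def __post_init__(self) -> None:
        self.abar = np.asarray(self.abar, dtype=float)
        d = self.abar.diagonal()
        if not np.allclose(d, -1.0, atol=1e-12):
            raise ValueError("normalised matrix must have uniform diagonal -1")
        off = self.abar - np.diag(d)
        if (off > 0).any():
            raise ValueError("off-diagonal entries must be <= 0")


def as_matrix(m) -> np.ndarray:
    """Return the underlying square array of a Jacobian, normalised matrix or array."""
    if isinstance(m, JacobianMatrix):
        return m.a
    if isinstance(m, NormalizedMatrix):
        return m.abar
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {arr.shape}")
    return arr


def energy_loss_web(contacts: ContactData, costs: CostParameters = DEFAULT_COSTS) -> EnergyLossWeb:
    """Build the energy-loss web f_ij from contest counts.

    Off-diagonal: f_ij = p_win*W_ij + p_loss*W_ji + p_draw*D_ij.
    Diagonal: each intraspecific overgrowth event is one win and one loss
    for the species, and tied outcomes are doubled because two colonies of
    the species are affected by a single recorded contest.
    """
    w = contacts.wins.astype(float)
    d = contacts.draws.astype(float)
    f = costs.p_win * w + costs.p_loss * w.T + costs.p_draw * d
    diag = (costs.p_win + costs.p_loss) * w.diagonal() + 2.0 * costs.p_draw * d.diagonal()
    np.fill_diagonal(f, diag)
    return EnergyLossWeb(list(contacts.species), f, costs)


def jacobian(
    web: EnergyLossWeb,
    abundance: np.ndarray,
    diag_fill_factor: float = 0.1,
    *,
    fill_mean_includes_zeros: bool = False,
) -> JacobianMatrix:
    """Per-capita interaction strengths a_ij = f_ij / B_j with diagonal filling.

    Any zero diagonal (no observed intraspecific competition) is replaced by
    ``diag_fill_factor`` times the mean Jacobian element, computed over the
    non-zero entries of the pre-fill matrix by default (set
    ``fill_mean_includes_zeros`` to average over all S^2 entries instead),
    and flagged in ``diag_estimated``.
    """
    b = np.asarray(abundance, dtype=float)
    if b.shape != (len(web.species),):
        raise ValueError("abundance length must match the species list")
    if (b < 1).any() or not np.isfinite(b).all():
        raise ValueError("every species needs an abundance >= 1 colony")
    if diag_fill_factor <= 0:
        raise ValueError("diag_fill_factor must be positive")
    a = web.f / b[np.newaxis, :]
    if not a.any():
        raise ValueError(
            "all interaction strengths are zero (no contests recorded); "
            "cannot define a mean for diagonal filling"
        )
    if fill_mean_includes_zeros:
        fill_mean = a.mean()
    else:
        fill_mean = a[a != 0].mean()
    estimated = a.diagonal() == 0.0
    a = a.copy()
    a[np.diag_indices_from(a)] = np.where(estimated, diag_fill_factor * fill_mean, a.diagonal())
    return JacobianMatrix(list(web.species), a, estimated, diag_fill_factor)


def normalize(j: JacobianMatrix | np.ndarray) -> NormalizedMatrix:
    """Divide each row by |a_ii|, giving a community matrix with diagonal -1."""
    a = as_matrix(j)
    d = a.diagonal()
    if (d >= 0).any():
        raise ValueError(
            "normalisation requires strictly negative diagonals; "
            "fill unobserved self-regulation terms first (see jacobian)"
        )
    abar = a / np.abs(d)[:, np.newaxis]
    np.fill_diagonal(abar, -1.0)
    species = j.species if isinstance(j, JacobianMatrix) else [f"sp{i}" for i in range(a.shape[0])]
    return NormalizedMatrix(list(species), abar)
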