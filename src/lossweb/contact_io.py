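"""Data model and file I/O for species-contact matrices.

A species-contact matrix records the outcomes of pairwise overgrowth
contests between colonies of sessile, encrusting species (e.g. bryozoans):
wins ``W_ij`` (colonies of species *i* overgrew colonies of species *j*),
draws ``D_ij`` (mutual overgrowth or growth cessation at the boundary),
and per-species colony abundances ``B_i``.

Two on-disk dialects are supported:

* **long** — a TSV with columns ``species_a``, ``species_b``, ``wins_a``,
  ``wins_b``, ``draws``; one row per unordered pair, plus optional diagonal
  rows (``species_a == species_b``) where ``wins_a`` counts intraspecific
  overgrowth events and ``draws`` counts intraspecific ties.
* **wide** — an S×S win-count matrix and an S×S draw-count matrix as
  headed CSV.

Abundances always travel in a separate TSV with columns ``species`` and
``colonies``; the species order of that file defines the species order of
the :class:`ContactData`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ContactData",
    "ParseError",
    "read_contacts",
    "read_contacts_wide",
    "write_contacts",
    "connectance",
    "win_loss_summary",
    "intraspecific_summary",
]


class ParseError(ValueError):
    """A contacts or abundance file could not be parsed."""


@dataclass
class ContactData:
    """Validated contest counts and abundances for one assemblage.

    Attributes
    ----------
    assemblage_id : str
        Free-text label of the assemblage.
    species : list of str
        Ordered species labels; the order is preserved through the whole
        pipeline so that downstream randomisations are reproducible.
    wins : (S, S) int array
        ``wins[i, j]`` = number of contests in which species *i* overgrew
        species *j*.  The diagonal counts intraspecific overgrowth events.
    draws : (S, S) int array
        Tied contests, one record per contest; symmetric off the diagonal.
    abundance : (S,) int array
        Colonies per species, all >= 1.
    """

    assemblage_id: str
    species: list[str]
    wins: np.ndarray
    draws: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.species = list(self.species)
        s = len(self.species)
        self.wins = np.asarray(self.wins, dtype=np.int64)
        self.draws = np.asarray(self.draws, dtype=np.int64)
        self.abundance = np.asarray(self.abundance, dtype=np.int64)
        if self.wins.shape != (s, s) or self.draws.shape != (s, s):
            raise ValueError(
                f"count matrices must be {s}x{s} to match the species list, "
                f"got wins {self.wins.shape} and draws {self.draws.shape}"
            )
        if self.abundance.shape != (s,):
            raise ValueError(f"abundance must have length {s}")
        if (self.wins < 0).any() or (self.draws < 0).any():
            raise ValueError("contest counts must be non-negative")
        if (self.abundance < 1).any():
            bad = [self.species[i] for i in np.flatnonzero(self.abundance < 1)]
            raise ValueError(f"abundance must be >= 1 colony for every species; offending: {bad}")
        asym = np.argwhere(self.draws != self.draws.T)
        asym = [tuple(ij) for ij in asym if ij[0] < ij[1]]
        if asym:
            pairs = [f"({self.species[i]}, {self.species[j]})" for i, j in asym]
            raise ValueError(f"draw counts must be symmetric off-diagonal; offending pairs: {pairs}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def n_contests(self, i: int, j: int) -> int:
        """Total contests N_ij = W_ij + W_ji + D_ij between species i and j."""
        if i == j:
            return int(self.wins[i, i] + self.draws[i, i])
        return int(self.wins[i, j] + self.wins[j, i] + self.draws[i, j])

    def index_of(self, label: str) -> int:
        return self.species.index(label)


_LONG_COLUMNS = ["species_a", "species_b", "wins_a", "wins_b", "draws"]


def _read_abundance(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if not {"species", "colonies"} <= set(df.columns):
        raise ParseError(f"{path}: abundance file needs columns 'species' and 'colonies'")
    species = [str(s) for s in df["species"]]
    if len(set(species)) != len(species):
        raise ParseError(f"{path}: duplicated species label in abundance file")
    return species, df["colonies"].to_numpy()


def read_contacts(
    contacts_path: str | Path,
    abundance_path: str | Path,
    *,
    dialect: str = "long",
    assemblage_id: str | None = None,
) -> ContactData:
    """Read a long-format contacts TSV plus its abundance TSV.

    The species universe and order come from the abundance file; pairs with
    no row in the contacts file get zero counts.  A contests file may be
    completely empty (header only).
    """
    if dialect not in ("long", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}; use read_contacts_wide for matrix CSVs")
    species, abund = _read_abundance(abundance_path)
    idx = {sp: i for i, sp in enumerate(species)}
    s = len(species)
    wins = np.zeros((s, s), dtype=np.int64)
    draws = np.zeros((s, s), dtype=np.int64)

    try:
        df = pd.read_csv(contacts_path, sep="\t", dtype={"species_a": str, "species_b": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_LONG_COLUMNS)
    missing = set(_LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{contacts_path}: missing columns {sorted(missing)}")

    seen: set[tuple[int, int]] = set()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            a, b = idx[row.species_a], idx[row.species_b]
        except KeyError as exc:
            raise ParseError(
                f"{contacts_path}, line {line_no}: species {exc} not in abundance file"
            ) from None
        try:
            wa, wb, d = int(row.wins_a), int(row.wins_b), int(row.draws)
        except (TypeError, ValueError):
            raise ParseError(f"{contacts_path}, line {line_no}: non-integer count") from None
        if min(wa, wb, d) < 0:
            raise ValueError(f"{contacts_path}, line {line_no}: negative count")
        key = (min(a, b), max(a, b))
        if key in seen:
            raise ParseError(
                f"{contacts_path}, line {line_no}: duplicate row for pair "
                f"({species[key[0]]}, {species[key[1]]})"
            )
        seen.add(key)
        if a == b:
            if wa != wb and wb != 0:
                raise ParseError(
                    f"{contacts_path}, line {line_no}: diagonal row must leave wins_b 0"
                )
            wins[a, a] = wa
            draws[a, a] = d
        else:
            wins[a, b] = wa
            wins[b, a] = wb
            draws[a, b] = draws[b, a] = d

    if assemblage_id is None:
        assemblage_id = Path(contacts_path).stem
    return ContactData(assemblage_id, species, wins, draws, abund)


def read_contacts_wide(
    wins_path: str | Path,
    draws_path: str | Path,
    abundance_path: str | Path,
    *,
    assemblage_id: str | None = None,
) -> ContactData:
    """Read the wide dialect: S×S win and draw count matrices as headed CSV.

    Rows and columns must be labelled with species names matching the
    abundance file.  A draw matrix with a count recorded on one side only is
    symmetrised (the missing mirror entry is filled); two conflicting
    non-zero mirror entries raise.
    """
    species, abund = _read_abundance(abundance_path)

    def _read_matrix(path: str | Path) -> np.ndarray:
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        try:
            df = df.loc[species, species]
        except KeyError:
            raise ParseError(f"{path}: matrix labels do not cover the abundance species") from None
        return df.to_numpy(dtype=np.int64)

    wins = _read_matrix(wins_path)
    draws = _read_matrix(draws_path)
    # symmetrise draws recorded on one side only
    one_sided = (draws == 0) & (draws.T > 0)
    draws = np.where(one_sided, draws.T, draws)
    conflict = np.argwhere((draws != draws.T) & (draws > 0) & (draws.T > 0))
    conflict = [tuple(ij) for ij in conflict if ij[0] < ij[1]]
    if conflict:
        pairs = [f"({species[i]}, {species[j]})" for i, j in conflict]
        raise ValueError(f"{draws_path}: conflicting draw counts for pairs {pairs}")
    if assemblage_id is None:
        assemblage_id = Path(wins_path).stem
    return ContactData(assemblage_id, species, wins, draws, abund)


def write_contacts(
    contacts: ContactData,
    contacts_path: str | Path,
    abundance_path: str | Path,
) -> None:
    """Write the long-format contacts TSV and the abundance TSV."""
    rows = []
    s = contacts.n_species
    for i in range(s):
        if contacts.wins[i, i] or contacts.draws[i, i]:
            rows.append(
                (contacts.species[i], contacts.species[i],
                 int(contacts.wins[i, i]), int(contacts.wins[i, i]),
                 int(contacts.draws[i, i]))
            )
        for j in range(i + 1, s):
            if contacts.n_contests(i, j) > 0:
                rows.append(
                    (contacts.species[i], contacts.species[j],
                     int(contacts.wins[i, j]), int(contacts.wins[j, i]),
                     int(contacts.draws[i, j]))
                )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(contacts_path, sep="\t", index=False)
    pd.DataFrame(
        {"species": contacts.species, "colonies": contacts.abundance}
    ).to_csv(abundance_path, sep="\t", index=False)


def connectance(contacts: ContactData) -> float:
    """Realised fraction of interspecific pairs with at least one contest.

    Counts unordered pairs {i, j}, i != j, with N_ij > 0 over S(S-1)/2.
    """
    s = contacts.n_species
    if s < 2:
        raise ValueError("connectance needs at least 2 species")
    n_active = sum(
        1
        for i in range(s)
        for j in range(i + 1, s)
        if contacts.n_contests(i, j) > 0
    )
    return n_active / (s * (s - 1) / 2)


def win_loss_summary(contacts: ContactData) -> pd.DataFrame:
    """Per-pair table of (W_ij, W_ji, D_ij, N_ij) for interacting pairs.

    Intraspecific contests are excluded here; see
    :func:`intraspecific_summary`.
    """
    rows = []
    s = contacts.n_species
    for i in range(s):
        for j in range(i + 1, s):
            n = contacts.n_contests(i, j)
            if n > 0:
                rows.append(
                    (contacts.species[i], contacts.species[j],
                     int(contacts.wins[i, j]), int(contacts.wins[j, i]),
                     int(contacts.draws[i, j]), n)
                )
    return pd.DataFrame(
        rows, columns=["species_a", "species_b", "wins_a", "wins_b", "draws", "n"]
    )


def intraspecific_summary(contacts: ContactData) -> pd.DataFrame:
    """Per-species intraspecific overgrowth events and ties."""
    return pd.DataFrame(
        {
            "species": contacts.species,
            "overgrowths": contacts.wins.diagonal(),
            "ties": contacts.draws.diagonal(),
        }
    )
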