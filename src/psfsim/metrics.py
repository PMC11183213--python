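"""Emergent community properties computed from simulation summaries.

All pre-invasion metrics (diversity, compositional change, average growth
rate) are taken over the resident species only, at time points that precede
the invasion event; invasibility is the invader's share of total community
biomass at the final step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import InteractionTable

__all__ = [
    "CommunitySummary",
    "EmptyCommunityError",
    "invader_percent_biomass",
    "inverse_simpson",
    "bray_curtis_change",
    "community_avg_growth_rate",
]


class EmptyCommunityError(ValueError):
    """A metric was requested for a community with no individuals/biomass."""


@dataclass
class CommunitySummary:
    """Species biomass and abundance vectors at one recorded time step.

    Vectors cover the residents followed by the invader (length
    ``n_resident + 1``).  Invader entries are zero before the invasion step.
    """

    step: int
    biomass_by_species: np.ndarray
    abundance_by_species: np.ndarray
    n_resident: int

    def __post_init__(self) -> None:
        b = np.asarray(self.biomass_by_species, dtype=float)
        a = np.asarray(self.abundance_by_species)
        if b.shape != a.shape or b.ndim != 1:
            raise ValueError("biomass and abundance vectors must match")
        if np.any(b < 0) or np.any(a < 0):
            raise ValueError("species totals must be non-negative")
        self.biomass_by_species = b
        self.abundance_by_species = a

    @property
    def resident_biomass(self) -> np.ndarray:
        return self.biomass_by_species[: self.n_resident]

    @property
    def resident_abundance(self) -> np.ndarray:
        return self.abundance_by_species[: self.n_resident]

    @property
    def invader_biomass(self) -> float:
        return float(self.biomass_by_species[self.n_resident])


def invader_percent_biomass(summary: CommunitySummary) -> float:
    """Invader share of total community biomass, in percent."""
    total = float(summary.biomass_by_species.sum())
    if total <= 0.0:
        raise EmptyCommunityError("no biomass in the community")
    return 100.0 * summary.invader_biomass / total


def _shares(summary: CommunitySummary, basis: str) -> np.ndarray:
    if basis == "biomass":
        v = summary.resident_biomass
    elif basis == "abundance":
        v = summary.resident_abundance.astype(float)
    else:
        raise ValueError("basis must be 'biomass' or 'abundance'")
    total = v.sum()
    if total <= 0.0:
        raise EmptyCommunityError("no resident individuals/biomass")
    return v / total


def inverse_simpson(summary: CommunitySummary, basis: str = "biomass") -> float:
    """Inverse Simpson diversity 1/D = 1 / sum(p_i^2) over resident species.

    Equals the species count for a perfectly even community and 1 for a
    monoculture.  Shares are biomass-based by default; pass
    ``basis='abundance'`` for individual-count shares.
    """
    p = _shares(summary, basis)
    return float(1.0 / np.sum(p * p))


def bray_curtis_change(
    summary_a: CommunitySummary, summary_b: CommunitySummary
) -> float:
    """Bray-Curtis dissimilarity between two resident biomass vectors:
    sum|x - y| / sum(x + y).  0 for identical composition, 1 for disjoint
    species sets."""
    x = summary_a.resident_biomass
    y = summary_b.resident_biomass
    denom = float(np.sum(x + y))
    if denom <= 0.0:
        raise EmptyCommunityError("both communities are empty")
    return float(np.sum(np.abs(x - y)) / denom)


def community_avg_growth_rate(
    summary: CommunitySummary,
    table: InteractionTable,
    basis: str = "abundance",
) -> float:
    """Expected establishment growth rate of a random resident recruit.

    With global dispersal a random propagule is of species *i* with
    probability ``p_i`` and lands on soil conditioned by species *j* with
    probability ``p_j``, so the community's average establishment rate is
    ``sum_ij p_i p_j rate(i, j)`` over the scenario's interaction table —
    a frequency-only measure of the pre-invasion community's productivity,
    bounded between the slow and fast rates.  Frequencies are
    individual-count based by default.
    """
    p = _shares(summary, basis)
    rates = table.resident_values()
    return float(p @ rates @ p)
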