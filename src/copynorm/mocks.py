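"""In silico mock communities with known GCN ground truth.

The validation design: communities of known cell abundances follow a power
law rank-abundance curve whose exponent is solved so the most abundant
species holds a chosen fraction of the community (20% by default). Member
genomes are drawn from a pool with known 16S GCN and genome length. Each
community is "sequenced" twice at the count level: an amplicon profile
(read probability proportional to cells x GCN — the copy-number bias
itself) and a shotgun profile (proportional to cells x genome length).
Correcting the amplicon profile with the true GCN should recover the cell
fractions; the shotgun profile, normalized by genome length, provides an
independent estimate of the same ground truth.

Read-level artifacts (sequencing errors, chimeras, primer mismatch) are not
simulated: the copy-number bias acts at the count level, which is what the
correction addresses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .profiles import CommunityProfile, OtuRecord

__all__ = [
    "GenomePoolEntry",
    "MockCommunity",
    "powerlaw_abundances",
    "random_genome_pool",
    "build_mock",
    "simulate_amplicon",
    "simulate_shotgun",
    "length_normalized_profile",
    "expected_profile",
]


@dataclass(frozen=True)
class GenomePoolEntry:
    species_id: str
    taxonomy: str
    gcn: float
    genome_length: int  # bp


@dataclass(frozen=True)
class MockSpecies:
    species_id: str
    taxonomy: str
    cell_abundance: float  # relative fraction, community sums to 1
    gcn: float
    genome_length: int


@dataclass
class MockCommunity:
    """Ranked species list with cell abundances summing to 1."""

    species: List[MockSpecies]
    seed: Optional[int] = None

    def __post_init__(self):
        total = sum(s.cell_abundance for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell abundances sum to {total}, expected 1")
        fracs = [s.cell_abundance for s in self.species]
        if any(a < b for a, b in zip(fracs, fracs[1:])):
            raise ValueError("species must be ranked by decreasing abundance")

    @property
    def cell_fractions(self) -> np.ndarray:
        return np.array([s.cell_abundance for s in self.species])

    @property
    def gcns(self) -> np.ndarray:
        return np.array([s.gcn for s in self.species])

    @property
    def genome_lengths(self) -> np.ndarray:
        return np.array([s.genome_length for s in self.species], dtype=float)


def powerlaw_abundances(richness: int, top_fraction: float = 0.20) -> np.ndarray:
    """Power-law rank-abundance vector p(r) ~ r^(-a), normalized to 1.

    The exponent ``a`` is solved by bisection so that the most abundant
    rank holds ``top_fraction`` of the community, i.e. sum_r r^(-a) =
    1 / top_fraction. Requires top_fraction >= 1/richness (the uniform
    community is the flattest power law).
    """
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if richness == 1:
        return np.array([1.0])  # a single species always holds everything
    if top_fraction < 1.0 / richness - 1e-12:
        raise ValueError(
            f"top_fraction {top_fraction} infeasible for richness {richness} "
            f"(minimum {1.0 / richness:.6g})")
    ranks = np.arange(1, richness + 1, dtype=float)

    def partial_sum(a: float) -> float:
        return float(np.sum(ranks ** -a))

    target = 1.0 / top_fraction
    lo, hi = 0.0, 50.0
    if partial_sum(lo) <= target:  # uniform (or infeasible within tolerance)
        return np.full(richness, 1.0 / richness)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = partial_sum(mid)
        if abs(s * top_fraction - 1.0) < 1e-10:
            lo = hi = mid
            break
        if s > target:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    p = ranks ** -a
    return p / p.sum()


def random_genome_pool(size: int, seed: Optional[int] = None,
                       n_phyla: int = 8) -> List[GenomePoolEntry]:
    """Seeded synthetic genome pool with realistic GCN (1-15 copies) and
    genome lengths (1.5-9 Mbp); species get nested taxonomic strings."""
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(size):
        phylum = int(rng.integers(n_phyla))
        genus = int(rng.integers(4))
        gcn = int(rng.integers(1, 16))
        length = int(rng.uniform(1.5e6, 9e6))
        tax = (f"k__Bacteria; p__P{phylum:02d}; c__C{phylum:02d}; "
               f"o__O{phylum:02d}; f__F{phylum:02d}_{genus}; "
               f"g__G{phylum:02d}_{genus}; s__S{i:05d}")
        pool.append(GenomePoolEntry(f"sp{i:05d}", tax, float(gcn), length))
    return pool


def build_mock(abundances: Sequence[float], genome_pool: Sequence[GenomePoolEntry],
               seed: Optional[int] = None) -> MockCommunity:
    """Assign pool genomes to abundance ranks by a seeded draw without
    replacement."""
    abundances = np.asarray(abundances, dtype=float)
    if len(genome_pool) < len(abundances):
        raise ValueError(
            f"genome pool of {len(genome_pool)} too small for richness "
            f"{len(abundances)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genome_pool), size=len(abundances), replace=False)
    species = [MockSpecies(genome_pool[i].species_id, genome_pool[i].taxonomy,
                           float(a), genome_pool[i].gcn,
                           genome_pool[i].genome_length)
               for a, i in zip(abundances, idx)]
    return MockCommunity(species, seed=seed)


def _draw_profile(mock: MockCommunity, probs: np.ndarray, depth: int,
                  seed: Optional[int], sample_id: str) -> CommunityProfile:
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, probs / probs.sum())
    otus = [OtuRecord(s.species_id, taxon_id=s.species_id, taxonomy=s.taxonomy)
            for s in mock.species]
    return CommunityProfile([sample_id], otus, counts[None, :].astype(float))


def simulate_amplicon(mock: MockCommunity, depth: int,
                      seed: Optional[int] = None,
                      sample_id: str = "amplicon") -> CommunityProfile:
    """Amplicon count profile: read probability ~ cells x GCN."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    probs = mock.cell_fractions * mock.gcns
    return _draw_profile(mock, probs, depth, seed, sample_id)


def simulate_shotgun(mock: MockCommunity, depth: int,
                     seed: Optional[int] = None,
                     sample_id: str = "shotgun") -> CommunityProfile:
    """Shotgun count profile: read probability ~ cells x genome length."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    probs = mock.cell_fractions * mock.genome_lengths
    return _draw_profile(mock, probs, depth, seed, sample_id)


def length_normalized_profile(shotgun: CommunityProfile,
                              genome_lengths: Sequence[float]) -> np.ndarray:
    """Length-normalize a shotgun profile to percent cell abundances.

    Dividing shotgun counts by genome length removes the genome-size bias,
    leaving an estimate proportional to cell abundance; this is the
    reference profile for amplicon-vs-metagenome comparisons.
    """
    lengths = np.asarray(genome_lengths, dtype=float)
    w = shotgun.counts[0] / lengths
    return w * 100.0 / w.sum()


def expected_profile(mock_or_templates, basis: str = "cell",
                     gcn: Optional[Sequence[float]] = None) -> np.ndarray:
    """Expected percent relative abundances of a mock community.

    ``cell`` basis normalizes the cell abundances to 100%. ``dna`` basis
    treats the input as 16S template quantities per species (a DNA pool):
    templates are divided by each species' GCN and then normalized to 100%.
    For the dna basis pass either a template vector plus ``gcn``, or a
    MockCommunity (templates taken as cells x GCN, so the result reduces to
    the cell fractions).
    """
    if basis == "cell":
        if not isinstance(mock_or_templates, MockCommunity):
            raise ValueError("cell basis expects a MockCommunity")
        return mock_or_templates.cell_fractions * 100.0
    if basis == "dna":
        if isinstance(mock_or_templates, MockCommunity):
            templates = (mock_or_templates.cell_fractions
                         * mock_or_templates.gcns)
            gcn = mock_or_templates.gcns
        else:
            templates = np.asarray(mock_or_templates, dtype=float)
            if gcn is None:
                raise ValueError("dna basis needs per-species GCN")
            gcn = np.asarray(gcn, dtype=float)
        if templates.sum() <= 0:
            raise ValueError("zero total templates")
        genomes = templates / gcn
        return genomes * 100.0 / genomes.sum()
    raise ValueError(f"unknown basis {basis!r}")
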