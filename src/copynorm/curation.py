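"""Curation of 16S rRNA gene copy number (GCN) records from sequenced genomes.

Genome catalogs report a 16S GCN per genome, but these records contain
errors: annotation pipelines miss genes on fragmented assemblies, collapse
near-identical copies, or call truncated pseudogenes. This module flags
suspicious catalog values by comparing them against two independent rRNA
gene predictors, assembly contiguity, and the within-species variation
observed among strains of the same species, and then attempts to resolve
each flagged record from the non-catalog evidence.

The within-species strain variation bound is the empirical line
``d <= 0.105 x + 0.720`` relating the maximal deviation ``d`` of a strain's
GCN from its species mean ``x``; a catalog value more than 1.2 times that
bound away from the species mean is treated as an outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomeRecord",
    "SpeciesReference",
    "CurationResult",
    "CurationSummary",
    "strain_bound",
    "flag_suspicious",
    "resolve_record",
    "curate_collection",
    "read_genome_table",
    "read_reference_table",
    "write_curation_table",
]

#: Catalog GCN values outside [GCN_MIN, GCN_MAX] are implausible for
#: bacteria/archaea (observed range is 1-15 copies).
GCN_MIN = 1
GCN_MAX = 15

#: Assemblies with average contig length below this (kbp) are too fragmented
#: to trust gene counts.
MIN_CONTIG_KBP = 200.0

#: 16S genes shorter than this (bp) are potentially truncated pseudogene
#: calls and are dropped on the resolution retry.
MIN_FULL_LENGTH_BP = 1220

#: Multiplier on the strain-variation bound for the outlier criterion.
OUTLIER_FACTOR = 1.2


@dataclass(frozen=True)
class GenomeRecord:
    """One sequenced genome's GCN evidence from multiple sources.

    Parameters
    ----------
    genome_id : str
        Opaque identifier of the genome record.
    species : str
        Species name used to match a :class:`SpeciesReference`.
    catalog_gcn : int
        16S GCN reported by the genome catalog.
    predictor_a_gcn, predictor_b_gcn : int
        16S gene counts from two independent rRNA gene predictors.
    gene_lengths : tuple of int
        Lengths (bp) of the predicted 16S genes.
    catalog_5s_gcn, catalog_23s_gcn : int
        Catalog counts of the other rRNA genes (usually co-occur in operons
        with the 16S gene, so they carry independent copy-number evidence).
    avg_contig_kbp : float
        Average contig length of the assembly, in kbp.
    scaffold_kbp : float
        Scaffold length of the assembly, in kbp.
    """

    genome_id: str
    species: str
    catalog_gcn: int
    predictor_a_gcn: int
    predictor_b_gcn: int
    gene_lengths: tuple = ()
    catalog_5s_gcn: int = 0
    catalog_23s_gcn: int = 0
    avg_contig_kbp: float = 1000.0
    scaffold_kbp: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("catalog_gcn", "predictor_a_gcn", "predictor_b_gcn",
                     "catalog_5s_gcn", "catalog_23s_gcn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if any(l <= 0 for l in self.gene_lengths):
            raise ValueError("gene lengths must be positive")
        if self.avg_contig_kbp <= 0 or self.scaffold_kbp <= 0:
            raise ValueError("assembly lengths must be positive")
        object.__setattr__(self, "gene_lengths", tuple(self.gene_lengths))


@dataclass(frozen=True)
class SpeciesReference:
    """Per-species mean GCN from a curated strain database."""

    species: str
    mean_gcn: float
    n_strains: int = 1

    def __post_init__(self) -> None:
        if self.mean_gcn <= 0:
            raise ValueError("mean_gcn must be positive")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")


@dataclass
class CurationResult:
    """Outcome of curating one genome record.

    ``status`` is ``clean`` (no flag fired), ``resolved`` (flags fired and a
    resolution rule produced a final value) or ``removed`` (unresolvable).
    ``final_gcn`` is absent (None) exactly when the record is removed.
    """

    genome_id: str
    status: str
    final_gcn: Optional[int] = None
    flags: frozenset = frozenset()
    resolution_rule: str = "none"

    def __post_init__(self) -> None:
        if (self.status == "removed") != (self.final_gcn is None):
            raise ValueError("status=removed iff final_gcn is absent")
        if self.status == "clean" and self.flags:
            raise ValueError("clean results carry no flags")


@dataclass
class CurationSummary:
    n_clean: int = 0
    n_resolved: int = 0
    n_removed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_clean + self.n_resolved + self.n_removed


def strain_bound(mean_gcn: float) -> float:
    """Maximal expected within-species GCN deviation for species mean ``x``.

    Returns ``f(x) = 0.105 * x + 0.720``, the upper bound on the difference
    between a species' mean GCN and the extremum among its strains, fitted
    across multi-strain species of a curated rRNA copy-number database.
    """
    if mean_gcn <= 0:
        raise ValueError(f"mean_gcn must be positive, got {mean_gcn}")
    return 0.105 * mean_gcn + 0.720


def _predictor_consistent(value: int, ref: SpeciesReference) -> bool:
    # "consistent with the reference database" = within the outlier bound
    # used for flagging, keeping a single notion of agreement.
    return abs(value - ref.mean_gcn) <= OUTLIER_FACTOR * strain_bound(ref.mean_gcn)


def flag_suspicious(record: GenomeRecord,
                    ref: Optional[SpeciesReference] = None) -> frozenset:
    """Return the set of suspicion criteria that fire for ``record``.

    The four criteria: catalog GCN out of the plausible range [1, 15]
    (``out_of_range``); average contig length below 200 kbp
    (``fragmented_assembly``); catalog GCN not identical to either
    predictor's count (``predictor_disagreement``); catalog GCN deviating
    from the species reference mean by more than 1.2 f(x)
    (``species_outlier``, only evaluated when a reference exists).
    """
    flags = set()
    if record.catalog_gcn < GCN_MIN or record.catalog_gcn > GCN_MAX:
        flags.add("out_of_range")
    if record.avg_contig_kbp < MIN_CONTIG_KBP:
        flags.add("fragmented_assembly")
    if (record.catalog_gcn != record.predictor_a_gcn
            or record.catalog_gcn != record.predictor_b_gcn):
        flags.add("predictor_disagreement")
    if ref is not None:
        bound = OUTLIER_FACTOR * strain_bound(ref.mean_gcn)
        if abs(record.catalog_gcn - ref.mean_gcn) > bound:
            flags.add("species_outlier")
    return frozenset(flags)


def _predictor_candidates(record: GenomeRecord,
                          gene_lengths: Sequence[int],
                          use_lengths: bool) -> list:
    """Candidate predictor GCN values, optionally recounted after dropping
    potentially truncated genes (< 1,220 bp)."""
    if use_lengths and gene_lengths:
        n_full = sum(1 for l in gene_lengths if l >= MIN_FULL_LENGTH_BP)
        return [n_full] if n_full >= 1 else []
    cands = []
    for v in (record.predictor_a_gcn, record.predictor_b_gcn):
        if v not in cands:
            cands.append(v)
    return cands


def _try_rules(record: GenomeRecord, ref: Optional[SpeciesReference],
               candidates: Iterable[int]):
    """Apply resolution rules 1-3 in order; return (gcn, rule) or None."""
    # Rule 1: predictor value consistent with the species reference.
    if ref is not None:
        for v in candidates:
            if GCN_MIN <= v <= GCN_MAX and _predictor_consistent(v, ref):
                return v, "predictor_vs_refdb"
    # Rule 2: no reference, but assembly scaffold is long enough to trust
    # the predictors (and they agree with each other).
    if ref is None and record.scaffold_kbp > MIN_CONTIG_KBP:
        cands = list(candidates)
        if len(set(cands)) == 1 and cands and GCN_MIN <= cands[0] <= GCN_MAX:
            return cands[0], "predictor_long_scaffold"
    # Rule 3: catalog 16S count is zero, but the 5S or 23S count matches
    # the species reference mean.
    if ref is not None and record.catalog_gcn == 0:
        for other in (record.catalog_5s_gcn, record.catalog_23s_gcn):
            if other >= GCN_MIN and abs(other - ref.mean_gcn) < 1e-9:
                return other, "other_rrna_genes"
    return None


def resolve_record(record: GenomeRecord,
                   ref: Optional[SpeciesReference] = None) -> CurationResult:
    """Curate one genome record: flag it, and resolve or remove it.

    Records with no flags are returned ``clean`` with the catalog value.
    Flagged records go through the resolution rules in order; if none fires,
    genes shorter than 1,220 bp (potentially truncated) are dropped from the
    predicted gene set and the rules are retried once. Unresolvable records
    are ``removed`` — never an exception.
    """
    flags = flag_suspicious(record, ref)
    if not flags:
        return CurationResult(record.genome_id, "clean", record.catalog_gcn)

    hit = _try_rules(record, ref, _predictor_candidates(record, record.gene_lengths, False))
    if hit is None and record.gene_lengths:
        retry = _predictor_candidates(record, record.gene_lengths, True)
        if retry:
            hit = _try_rules(record, ref, retry)
            if hit is not None:
                hit = (hit[0], "truncated_gene_retry")
    if hit is None:
        return CurationResult(record.genome_id, "removed", None, flags, "none")
    gcn, rule = hit
    return CurationResult(record.genome_id, "resolved", int(gcn), flags, rule)


def curate_collection(records: Sequence[GenomeRecord],
                      refs: Mapping[str, SpeciesReference] = None):
    """Curate every record; returns (results, summary).

    ``refs`` maps species name to :class:`SpeciesReference`; species absent
    from the map simply skip the outlier criterion and reference-based rules.
    Duplicate genome ids are rejected.
    """
    refs = refs or {}
    seen = set()
    for r in records:
        if r.genome_id in seen:
            raise ValueError(f"duplicate genome_id: {r.genome_id}")
        seen.add(r.genome_id)
    results = [resolve_record(r, refs.get(r.species)) for r in records]
    summary = CurationSummary(
        n_clean=sum(1 for r in results if r.status == "clean"),
        n_resolved=sum(1 for r in results if r.status == "resolved"),
        n_removed=sum(1 for r in results if r.status == "removed"),
    )
    return results, summary


# ---------------------------------------------------------------------------
# Tab-delimited I/O


def read_genome_table(path) -> list:
    """Read genome records from a tab-delimited table (one row per genome;
    gene_lengths as comma-separated bp)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        lengths = ()
        raw = row.get("gene_lengths")
        if isinstance(raw, str) and raw.strip():
            lengths = tuple(int(x) for x in raw.split(","))
        records.append(GenomeRecord(
            genome_id=row["genome_id"],
            species=row["species"],
            catalog_gcn=int(row["catalog_gcn"]),
            predictor_a_gcn=int(row["predictor_a_gcn"]),
            predictor_b_gcn=int(row["predictor_b_gcn"]),
            gene_lengths=lengths,
            catalog_5s_gcn=int(row.get("catalog_5s_gcn", 0) or 0),
            catalog_23s_gcn=int(row.get("catalog_23s_gcn", 0) or 0),
            avg_contig_kbp=float(row["avg_contig_kbp"]),
            scaffold_kbp=float(row["scaffold_kbp"]),
        ))
    return records


def read_reference_table(path) -> dict:
    """Read a species reference table: species, mean_gcn, n_strains."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(row["species"]): SpeciesReference(str(row["species"]),
                                              float(row["mean_gcn"]),
                                              int(row["n_strains"]))
        for _, row in df.iterrows()
    }


def write_curation_table(results: Sequence[CurationResult], path) -> None:
    df = pd.DataFrame({
        "genome_id": [r.genome_id for r in results],
        "status": [r.status for r in results],
        "final_gcn": [r.final_gcn if r.final_gcn is not None else "" for r in results],
        "flags": [",".join(sorted(r.flags)) for r in results],
        "resolution_rule": [r.resolution_rule for r in results],
    })
    df.to_csv(path, sep="\t", index=False)
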