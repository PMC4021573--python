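"""GCN bias correction of amplicon community profiles and qPCR totals.

A 16S amplicon read count is proportional to (cells x gene copies per
genome), so organisms with many 16S copies are over-represented. Given a
pre-computed GCN lookup, each OTU count c_i is weighted by the inverse of
its copy number g_i and renormalized:

    r_i = (c_i / g_i) * 100 / sum_j (c_j / g_j)

OTUs without any taxonomic assignment receive the community-average GCN so
they do not distort the relative abundances of the assigned OTUs. The
community average is the read-weighted mean

    g_bar = sum_i c_i / sum_i (c_i / g_i)

so that a qPCR template count divided by g_bar yields the genome (cell)
count exactly when reads are proportional to genomes x GCN.

Supported OTU-table dialects: plain tab-delimited, JSON BIOM v1.0 and
QIIME classic; output is written back in the input dialect.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .trait import GcnLookup

logger = logging.getLogger(__name__)

__all__ = [
    "OtuRecord",
    "CommunityProfile",
    "CorrectedProfile",
    "ProfileParseError",
    "CorrectionError",
    "read_profile",
    "write_profile",
    "lookup_gcn",
    "community_average_gcn",
    "correct_profile",
    "read_qpcr",
    "correct_qpcr",
    "rarefy",
]


class ProfileParseError(ValueError):
    """OTU table could not be parsed; message names the offending location."""


class CorrectionError(ValueError):
    """Correction impossible; message names the offending sample."""


@dataclass(frozen=True)
class OtuRecord:
    otu_id: str
    taxon_id: Optional[str] = None
    taxonomy: Optional[str] = None


@dataclass
class CommunityProfile:
    """Samples x OTUs count matrix with per-OTU taxonomic metadata."""

    samples: List[str]
    otus: List[OtuRecord]
    counts: np.ndarray  # shape (n_samples, n_otus), non-negative
    source_format: str = "tabular"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.samples), len(self.otus)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.otus)} OTUs")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def otu_ids(self) -> List[str]:
        return [o.otu_id for o in self.otus]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=self.otu_ids)


@dataclass
class CorrectedProfile:
    """GCN-corrected relative abundances (percent) plus per-sample average GCN."""

    samples: List[str]
    otus: List[OtuRecord]
    abundance: np.ndarray          # percent, rows sum to 100
    average_gcn: Dict[str, float]  # per-sample read-weighted mean GCN
    applied_gcn: np.ndarray        # per sample x OTU, the g_i actually used
    source_format: str = "tabular"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.samples,
                            columns=[o.otu_id for o in self.otus])


# ---------------------------------------------------------------------------
# Readers

_UNASSIGNED = {"", "unassigned", "unclassified", "none", "na", "no blast hit"}


def _clean_taxonomy(raw) -> Optional[str]:
    if raw is None:
        return None
    s = str(raw).strip()
    return None if s.lower() in _UNASSIGNED else s


def _detect_format(text: str) -> str:
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return "biom_json"
    for line in stripped.splitlines():
        if line.startswith("#OTU ID"):
            return "qiime_classic"
        if not line.startswith("#"):
            break
    return "tabular"


def _parse_tabular(text: str, fmt: str) -> CommunityProfile:
    lines = [l for l in text.splitlines() if l.strip()]
    header = None
    data_lines = []
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID"):
            header = line.lstrip("#").split("\t")
            header[0] = "OTU ID"
        elif line.startswith("#"):
            continue
        elif header is None:
            header = line.split("\t")
        else:
            data_lines.append((i + 1, line))
    if header is None or not data_lines:
        raise ProfileParseError("no header or data rows found")
    has_tax = header[-1].strip().lower() in {"taxonomy", "consensus lineage",
                                             "consensuslineage"}
    sample_ids = header[1:-1] if has_tax else header[1:]
    if not sample_ids:
        raise ProfileParseError("no sample columns in header")
    otus, rows = [], []
    for lineno, line in data_lines:
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ProfileParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(parts)}")
        tax = _clean_taxonomy(parts[-1]) if has_tax else None
        vals = parts[1:-1] if has_tax else parts[1:]
        try:
            row = [float(v) for v in vals]
        except ValueError as e:
            raise ProfileParseError(f"line {lineno}: non-numeric count ({e})")
        if any(v < 0 for v in row):
            raise ProfileParseError(f"line {lineno}: negative count")
        otus.append(OtuRecord(parts[0], taxon_id=parts[0], taxonomy=tax))
        rows.append(row)
    counts = np.array(rows, dtype=float).T  # rows were per-OTU
    return CommunityProfile(list(sample_ids), otus, counts, source_format=fmt)


def _parse_biom_json(text: str) -> CommunityProfile:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ProfileParseError(f"invalid BIOM JSON at offset {e.pos}: {e.msg}")
    n_otus, n_samples = doc["shape"]
    otus = []
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy")
        if isinstance(tax, list):
            tax = "; ".join(str(t) for t in tax)
        otus.append(OtuRecord(str(row["id"]),
                              taxon_id=str(meta.get("taxon_id", row["id"])),
                              taxonomy=_clean_taxonomy(tax)))
    samples = [str(c["id"]) for c in doc["columns"]]
    mat = np.zeros((n_otus, n_samples))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    if np.any(mat < 0):
        raise ProfileParseError("negative count in BIOM matrix")
    return CommunityProfile(samples, otus, mat.T, source_format="biom_json")


def read_profile(path, format: str = "autodetect") -> CommunityProfile:
    """Read an OTU table (tabular, JSON BIOM v1.0 or QIIME classic).

    Autodetection: leading '{' means BIOM, a '#OTU ID' header line means
    QIIME classic, anything else is plain tabular. Taxonomy is taken from a
    trailing ``taxonomy`` column or the BIOM row metadata.
    """
    with open(path) as fh:
        text = fh.read()
    if format == "autodetect":
        format = _detect_format(text)
    if format == "biom_json":
        return _parse_biom_json(text)
    if format in ("tabular", "qiime_classic"):
        return _parse_tabular(text, format)
    raise ProfileParseError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Correction


def lookup_gcn(otu: OtuRecord, lookup: GcnLookup, mode: str = "phylogenetic"
               ) -> Optional[float]:
    """Resolve one OTU's GCN from the lookup.

    ``phylogenetic`` mode keys on the OTU's taxon id; ``taxonomic`` mode
    keys on the taxonomic string, stripping the deepest rank until a match.
    Returns None when nothing matches or the OTU is unassigned.
    """
    if mode == "phylogenetic":
        if otu.taxon_id is None:
            return None
        return lookup.get_by_id(otu.taxon_id)
    if mode == "taxonomic":
        if otu.taxonomy is None:
            return None
        return lookup.get_by_string(otu.taxonomy)
    raise ValueError(f"unknown mode {mode!r}")


def community_average_gcn(counts: np.ndarray, gcn: np.ndarray) -> float:
    """Read-weighted average GCN: g_bar = sum(c_i) / sum(c_i / g_i).

    With this definition a qPCR template count divided by g_bar equals the
    genome count exactly whenever reads are proportional to genomes x GCN.
    """
    counts = np.asarray(counts, dtype=float)
    gcn = np.asarray(gcn, dtype=float)
    if counts.shape != gcn.shape:
        raise ValueError("counts and gcn vectors must be aligned")
    total = counts.sum()
    if total <= 0:
        raise ValueError("average GCN undefined: all counts are zero")
    return float(total / np.sum(counts / gcn))


def correct_profile(profile: CommunityProfile, lookup: GcnLookup,
                    mode: str = "phylogenetic") -> CorrectedProfile:
    """Apply the GCN correction to every sample of a profile.

    Per sample: resolve g_i for each OTU; compute the community average
    g_bar from the assigned OTUs; give unassigned/unmatched OTUs g_i =
    g_bar; then r_i = (c_i/g_i) * 100 / sum_j (c_j/g_j). Raises
    :class:`CorrectionError` if a sample has no resolvable OTU with reads.
    """
    resolved = np.array([np.nan if (g := lookup_gcn(o, lookup, mode)) is None
                         else g for o in profile.otus], dtype=float)
    n_unmatched = sum(1 for o, g in zip(profile.otus, resolved)
                      if np.isnan(g) and (o.taxonomy or o.taxon_id))
    if n_unmatched:
        logger.warning("%d OTUs with taxonomic metadata missed the lookup; "
                       "treated as unassigned (community-average GCN)", n_unmatched)
    abundance = np.zeros_like(profile.counts)
    applied = np.zeros_like(profile.counts)
    averages: Dict[str, float] = {}
    for s, sample in enumerate(profile.samples):
        c = profile.counts[s]
        assigned = ~np.isnan(resolved)
        if not np.any(assigned & (c > 0)):
            raise CorrectionError(
                f"sample {sample!r}: no OTU with reads has a resolvable GCN")
        gbar = community_average_gcn(c[assigned], resolved[assigned])
        g = np.where(assigned, resolved, gbar)
        weighted = c / g
        abundance[s] = weighted * 100.0 / weighted.sum()
        applied[s] = g
        averages[sample] = gbar
    return CorrectedProfile(list(profile.samples), list(profile.otus),
                            abundance, averages, applied,
                            source_format=profile.source_format)


# ---------------------------------------------------------------------------
# qPCR


def read_qpcr(path) -> Dict[str, float]:
    """Read a tab-delimited qPCR table: sample <TAB> template count."""
    out: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ProfileParseError(f"qPCR line {lineno}: expected 2 fields")
            v = float(parts[1])
            if v < 0:
                raise ProfileParseError(f"qPCR line {lineno}: negative count")
            out[parts[0]] = v
    return out


def correct_qpcr(qpcr: Mapping[str, float],
                 averages: Mapping[str, float]) -> Dict[str, float]:
    """Convert 16S template counts to genome counts: templates / g_bar."""
    out = {}
    for sample, templates in qpcr.items():
        if sample not in averages:
            raise CorrectionError(f"no average GCN for qPCR sample {sample!r}")
        out[sample] = templates / averages[sample]
    return out


# ---------------------------------------------------------------------------
# Rarefaction


def rarefy(profile: CommunityProfile, depth: int, repetitions: int = 100,
           seed: Optional[int] = None) -> CommunityProfile:
    """Rarefy each sample to ``depth`` reads, averaging over repeated
    subsamples drawn without replacement.

    Samples with fewer than ``depth`` total reads pass through unchanged
    with a warning. Counts must be integers.
    """
    counts = profile.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts, dtype=float)
    for s, sample in enumerate(profile.samples):
        total = int(counts[s].sum())
        if total < depth:
            warnings.warn(f"sample {sample!r} has {total} < {depth} reads; "
                          "left unrarefied")
            out[s] = counts[s]
            continue
        if total == depth:
            out[s] = counts[s]
            continue
        acc = np.zeros(counts.shape[1])
        for _ in range(repetitions):
            acc += rng.multivariate_hypergeometric(counts[s], depth)
        out[s] = acc / repetitions
    return CommunityProfile(list(profile.samples), list(profile.otus), out,
                            source_format=profile.source_format)


# ---------------------------------------------------------------------------
# Writers


def _write_tabular(profile, path, fmt: str, values: np.ndarray) -> None:
    otus = profile.otus
    has_tax = any(o.taxonomy for o in otus)
    with open(path, "w") as fh:
        cols = ["#OTU ID" if fmt == "qiime_classic" else "OTU ID"]
        cols += list(profile.samples)
        if has_tax:
            cols.append("taxonomy")
        fh.write("\t".join(cols) + "\n")
        for j, otu in enumerate(otus):
            row = [otu.otu_id] + [repr(float(values[s, j]))
                                  for s in range(len(profile.samples))]
            if has_tax:
                row.append(otu.taxonomy or "")
            fh.write("\t".join(row) + "\n")


def _write_biom_json(profile, path, values: np.ndarray) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "copynorm",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [len(profile.otus), len(profile.samples)],
        "rows": [{"id": o.otu_id,
                  "metadata": ({"taxonomy": o.taxonomy.split("; ")}
                               if o.taxonomy else None)}
                 for o in profile.otus],
        "columns": [{"id": s, "metadata": None} for s in profile.samples],
        "data": values.T.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_profile(profile, path, format: Optional[str] = None) -> None:
    """Write a (corrected or raw) profile in the given dialect.

    ``format`` defaults to the profile's source format, so a corrected
    table comes back in the same dialect it was read in. For corrected
    profiles the per-sample average GCN is emitted to a side-car TSV at
    ``<path>.avg_gcn.tsv``.
    """
    fmt = format or profile.source_format
    values = profile.abundance if isinstance(profile, CorrectedProfile) \
        else profile.counts
    if fmt == "biom_json":
        _write_biom_json(profile, path, values)
    elif fmt in ("tabular", "qiime_classic"):
        _write_tabular(profile, path, fmt, values)
    else:
        raise ProfileParseError(f"unknown format {fmt!r}")
    if isinstance(profile, CorrectedProfile):
        with open(f"{path}.avg_gcn.tsv", "w") as fh:
            fh.write("#sample\taverage_gcn\n")
            for s in profile.samples:
                fh.write(f"{s}\t{profile.average_gcn[s]:.10g}\n")
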