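# copynorm

16S rRNA gene copy number (GCN) estimation on reference phylogenies and
copy-number bias correction of amplicon community profiles and qPCR
abundance estimates.

## The problem

Amplicon surveys count 16S rRNA gene reads, not cells. Bacterial genomes
carry anywhere from 1 to 15 copies of the gene (archaea up to ~5), so a raw
OTU table over-represents high-copy organisms, and a qPCR template count
over-states the number of genomes. Both biases are correctable if every
taxon's GCN is known — but only a small minority of species have sequenced
genomes. Because GCN carries strong phylogenetic signal, the copy number of
an unsequenced organism can be estimated from its sequenced relatives on a
reference tree.

`copynorm` is aimed at microbial ecologists who want quantitative community
profiles: it pre-computes GCN estimates for every tip and taxon of a
reference phylogeny, then corrects OTU tables and qPCR totals against that
lookup.

## The method

**Estimation.** Tips with sequenced genomes carry empirical GCN (genomes
mapping to one tip are averaged). Ancestral values are reconstructed with
Felsenstein's phylogenetically independent contrasts (PIC): for a node *k*
with daughters *i, j* carrying values *x_i, x_j* on (adjusted) branch
lengths *v_i, v_j*,

    x_k = (x_i/v_i + x_j/v_j) / (1/v_i + 1/v_j),   v_k' = v_k + v_i v_j/(v_i + v_j).

At the root this recursion yields the maximum-likelihood root state under
Brownian motion. To predict an *unsequenced tip*, the tree is rerooted at
that tip's attachment node and the PIC root estimate becomes the
prediction — equivalent to the GLS conditional expectation under Brownian
motion. Per-taxon values are weighted averages of the node estimates
mapping to the taxon, with empirical values displacing reconstructed ones.
The strength of the phylogenetic signal is quantified by Pagel's λ with a
likelihood-ratio test against λ = 0.

**Correction.** Given per-OTU copy numbers *g_i* and read counts *c_i*, the
corrected relative abundance is

    r_i = (c_i/g_i) · 100 / Σ_j (c_j/g_j),

with unassigned OTUs receiving the community-average GCN
ḡ = Σc_i / Σ(c_i/g_i) so they do not distort the assigned OTUs' ratios. A
qPCR template count divided by ḡ estimates the genome (cell) count.

**Validation.** A simulator builds power-law mock communities with known
cell abundances, GCNs and genome lengths, and "sequences" them at the count
level (amplicon reads ∝ cells × GCN, shotgun reads ∝ cells × genome
length). Hellinger-transformed Euclidean distances and Mann–Whitney tests
quantify how much the correction moves profiles toward the truth.

## Worked example

```python
import numpy as np
from copynorm import (CommunityProfile, GcnLookup, OtuRecord,
                      correct_profile, correct_qpcr)

otus = [OtuRecord("otu_highcopy", taxon_id="otu_highcopy"),
        OtuRecord("otu_lowcopy", taxon_id="otu_lowcopy")]
profile = CommunityProfile(["digester"], otus, np.array([[20000.0, 10000.0]]))
lookup = GcnLookup(id_map={"otu_highcopy": 2.0, "otu_lowcopy": 1.0})

corrected = correct_profile(profile, lookup)
genomes = correct_qpcr({"digester": 30000.0}, corrected.average_gcn)
```

prints (see `examples/correct_otu_table.py`):

```
raw read fractions      : [0.66666667 0.33333333]
corrected abundance (%) : [50. 50.]
community average GCN   : 1.5
qPCR templates / avg GCN: 20000.0 genomes
```

Two organisms contributed 10,000 cells each, but the two-copy organism got
twice the reads; the correction restores the 50/50 composition, and the
30,000 measured gene templates divided by the average copy number 1.5
return the true 20,000 genomes.

The other scripts under `examples/` each demonstrate one capability:
`infer_gcn_from_tree.py` (ancestral reconstruction and tip prediction),
`phylogenetic_signal.py` (Pagel's λ), `mock_validation.py` (the mock
community benchmark) and `curate_genomes.py` (curation of genome records).

## Command line

```sh
copynorm correct -i otu_table.tsv -l lookup.tsv -m phylo -q qpcr.tsv -o corrected.tsv
copynorm validate --observed obs.tsv --expected exp.tsv -o report.tsv
```

`correct` reads tabular, JSON BIOM v1.0 or QIIME classic tables
(autodetected), writes the corrected table in the same dialect plus a
side-car TSV of per-sample average GCNs, and optionally divides qPCR
template counts by those averages.

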