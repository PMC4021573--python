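"""Correct an amplicon OTU table and a qPCR total for copy-number bias.

Two organisms contribute the same number of cells, but one carries two 16S
gene copies per genome and the other one: the raw reads over-represent the
high-copy organism 2:1. Correcting with the known copy numbers restores the
50/50 cell composition, and dividing the qPCR template count by the
community-average copy number converts gene templates into genome (cell)
counts.
"""

import numpy as np

from copynorm import (CommunityProfile, GcnLookup, OtuRecord,
                      correct_profile, correct_qpcr)

# 10,000 cells each; reads ~ cells x GCN -> 20,000 vs 10,000 reads
otus = [OtuRecord("otu_highcopy", taxon_id="otu_highcopy"),
        OtuRecord("otu_lowcopy", taxon_id="otu_lowcopy")]
profile = CommunityProfile(["digester"], otus, np.array([[20000.0, 10000.0]]))
lookup = GcnLookup(id_map={"otu_highcopy": 2.0, "otu_lowcopy": 1.0})

corrected = correct_profile(profile, lookup)
print("raw read fractions      :", profile.counts[0] / profile.counts[0].sum())
print("corrected abundance (%) :", np.round(corrected.abundance[0], 2))
print("community average GCN   :", round(corrected.average_gcn["digester"], 4))

# 30,000 16S templates measured by qPCR = 20,000 genomes carrying 1.5 copies
genomes = correct_qpcr({"digester": 30000.0}, corrected.average_gcn)
print("qPCR templates / avg GCN:", round(genomes["digester"], 1), "genomes")
print("-> equal cell abundances and the true genome count are recovered")
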