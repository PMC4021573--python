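"""Flag and resolve suspicious 16S copy-number records.

A catalog record of zero 16S genes is implausible; if two independent rRNA
predictors agree with the species' strain-database mean, their value
replaces the catalog's. Records whose evidence is mutually inconsistent are
removed rather than guessed.
"""

from copynorm import GenomeRecord, SpeciesReference, curate_collection

records = [
    # clean: catalog and both predictors agree
    GenomeRecord("genomeA", "Escherichia sp.", 7, 7, 7,
                 avg_contig_kbp=900, scaffold_kbp=4600),
    # zeroed catalog entry, predictors consistent with the species mean
    GenomeRecord("genomeB", "Bacillus sp.", 0, 9, 9,
                 gene_lengths=(1540,) * 9, avg_contig_kbp=700,
                 scaffold_kbp=5100),
    # everything disagrees, fragmented assembly, no reference: unresolvable
    GenomeRecord("genomeC", "Candidatus x", 0, 3, 7,
                 gene_lengths=(800, 900), avg_contig_kbp=120,
                 scaffold_kbp=150),
]
refs = {"Escherichia sp.": SpeciesReference("Escherichia sp.", 7.0, 5),
        "Bacillus sp.": SpeciesReference("Bacillus sp.", 9.2, 3)}

results, summary = curate_collection(records, refs)
for r in results:
    flags = ",".join(sorted(r.flags)) or "-"
    print(f"{r.genome_id}: {r.status:8s} gcn={r.final_gcn} "
          f"rule={r.resolution_rule} flags={flags}")
print(f"summary: {summary.n_clean} clean, {summary.n_resolved} resolved, "
      f"{summary.n_removed} removed")
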