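"""Estimate 16S copy numbers for every node and unsequenced tip of a tree.

Only two of four species have sequenced genomes. Independent contrasts
reconstruct the ancestral copy numbers, and rerooting the tree at each
unsequenced tip's attachment point turns the same recursion into a
prediction for that tip. The aggregated per-taxon values form the lookup
table the correction engine consumes.
"""

from copynorm import (TraitTree, build_lookup, map_genomes_to_tips,
                      pic_ancestral_states, predict_unknown_tips)

newick = "((A:1.0,B:2.0)g__Alpha:1.0,(C:1.0,D:1.0)g__Beta:2.0)root;"
tree = TraitTree.from_newick(newick)

# two genomes map to tip A (GCN 4 and 6 -> mean 5), one genome to tip C
traits = map_genomes_to_tips([("gen1", "A", 4.0), ("gen2", "A", 6.0),
                              ("gen3", "C", 2.0)])
print("tip A empirical mean:", traits["A"].gcn, "(weight", traits["A"].weight, ")")

predictions = predict_unknown_tips(tree, traits)
for tip, est in sorted(predictions.items()):
    print(f"predicted GCN for unsequenced tip {tip}: {est.gcn:.3f} "
          f"(from {est.weight} empirical values)")

lookup = build_lookup(tree, traits)
print("lookup (taxon-id keyed):",
      {k: round(v, 3) for k, v in sorted(lookup.id_map.items())})
print("-> tips near A pull toward 5 copies, tips near C toward 2")
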