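"""In-silico mate-pair scaffolding of a fragmented toy genome.

Fragments a 100 kb random genome into 20 contigs with scrambled orientations,
simulates mate-pair libraries at 1-20 kb inserts (150 bp reads, 30x per
library), scaffolds hierarchically from the smallest insert upward, and
scores the result against the known truth layout.
"""

import popkit as pk

genome = pk.random_genome(100_000, seed=61)
contigs, layout = pk.fragment_genome(genome, 20, seed=62)
print(f"genome {len(genome)} bp -> {len(contigs)} contigs, "
      f"N50 {pk.n50(len(s) for s in contigs.values())} bp")

pairs = pk.generate_mate_pairs(genome, pk.MatePairParams(seed=63))
print(f"simulated {len(pairs)} mate pairs across "
      f"{len(set(p.insert_nominal for p in pairs))} insert-size libraries")

result, composition = pk.scaffold_pipeline(contigs, pairs)
ev = pk.evaluate_layouts(composition, layout)
print(f"\nscaffolds: {len(result.scaffolds)}  "
      f"N50 {result.n50_before} -> {result.n50_after} bp")
print(f"joins vs truth: recall {ev['recall']:.2%}, "
      f"precision {ev['precision']:.2%} "
      f"({ev['n_correct']}/{ev['n_truth']} adjacencies)")
print("Recall near 100% with precision 1.0 means the link graph ordered and "
      "oriented every contig correctly; N50 grows roughly to genome length.")
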