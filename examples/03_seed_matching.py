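"""From guide strands to seeds to 3' UTR seed matches.

Extracts the 6mer seed (guide positions 2-7) from vendor-format siRNA
sequences, maps each seed to its mRNA-side seed match (reverse
complement), and counts match occurrences in a set of synthetic UTRs.
"""

import seedtox as st

guides = {
    "siNT1": "rUrUrArGrUrCrGrArCrArUrGrUrArArArCrCrAAA",
    "siGGCAGU": "rUrGrGrCrArGrUrArCrArUrGrUrArArArCrCrAAA",
    "siGGGGGC": "rUrGrGrGrGrGrCrArCrArUrGrUrArArArCrCrAAA",
}
for name, antisense in guides.items():
    seed = st.extract_seed(antisense)
    print(f"{name}: seed {seed} -> 3' UTR seed match {st.seed_to_match(seed)}")
print("-> the toxic siGGGGGC engages GCCCCC sites, siGGCAGU engages ACUGCC.")

seqs, de = st.gen_transcriptome(st.TranscriptomeGenerator(n_genes=50, rng_seed=3))
index = st.build_match_index(seqs, words=["GCCCCC"])
has, has_not = index.genes_with_match("GCCCCC")
print(f"\n{len(has)} of {len(index.genes)} synthetic UTRs carry >= 1 GCCCCC")
gene = has[0]
print(f"example {gene}: {index.count(gene, 'GCCCCC')} occurrence(s) at "
      f"0-based positions {index.positions(gene, 'GCCCCC')}")
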