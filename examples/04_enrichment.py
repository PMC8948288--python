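"""Detect seed-match-driven downregulation in a ranked gene list.

Simulates a transcriptome where each planted GCCCCC match knocks a gene's
log2 fold change down by 1, then runs the three detection views: the
hypergeometric k-mer landscape, the eCDF/K-S shift test and a pre-ranked
enrichment score of the planted target set.
"""

import seedtox as st
from seedtox.alphabet import all_kmers

seqs, de = st.gen_transcriptome(
    st.TranscriptomeGenerator(n_genes=1000, beta_match=1.0, sigma=0.5, rng_seed=9)
)
index = st.build_match_index(seqs, words=all_kmers(6))
ranked = st.RankedGeneList.from_table(de)  # most downregulated first

land = st.sylamer_landscape(ranked, index, step=100)
word, peak = land.max_word()
print(f"landscape max: word {word} at -log10 p = {peak:.1f} "
      f"(Bonferroni line {land.bonferroni_threshold:.2f})")
print("-> the planted seed match GCCCCC should tower over the line; any "
      "other word staying below it indicates word-level specificity.")

with_fc = de.loc[de["match_count"] > 0, "log2FC"]
without_fc = de.loc[de["match_count"] == 0, "log2FC"]
res = st.ecdf_ks(with_fc, without_fc)
print(f"\neCDF shift: D = {res.D:.3f}, one-sided K-S p = {res.p:.2g} "
      f"({res.n_with} with vs {res.n_without} without a match)")
print("-> match-containing genes sit left of the rest: seed-mediated "
      "repression.")

targets = set(de.loc[de["match_count"] > 0, "gene"])
es = st.preranked_es(ranked, targets, n_perm=1000, rng_seed=1)
print(f"\npre-ranked enrichment of the {es.hits} match-containing genes: "
      f"ES = {es.ES:.3f}, permutation p = {es.p_perm:.4f}")
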