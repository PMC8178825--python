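"""Score two competing assemblies of the same genome on the four-score card.

Size score is 1 - |s - G|/G against the estimated haploid genome size G;
completeness averages the min-max-normalized single-copy BUSCO count and
k-mer score K = 1 - |k_obs - 50|/50 over the declared comparison set; N50
is reported raw (and normalized when a context is given).
"""

from covhap import (
    NormalizationContext,
    ScoreInputs,
    kmer_score,
    scorecard,
    simulate_contig_lengths,
)

G = 102_000_000  # estimated haploid genome size (bases)

# assembly A: near-right size, moderately contiguous, well collapsed
# assembly B: oversized (uncollapsed haplotigs), k-mer completeness too high
a = ScoreInputs(
    contig_lengths=simulate_contig_lengths(120, 105_000_000, seed=1),
    genome_size=G, kmer_completeness=52.0, busco_single=699,
)
b = ScoreInputs(
    contig_lengths=simulate_contig_lengths(400, 160_000_000, seed=2),
    genome_size=G, kmer_completeness=73.5, busco_single=640,
)

ctx_busco = NormalizationContext.from_values([a.busco_single, b.busco_single])
ctx_kmer = NormalizationContext.from_values(
    [kmer_score(a.kmer_completeness), kmer_score(b.kmer_completeness)]
)

for name, inputs, hap in (("A", a, 0.92), ("B", b, 0.62)):
    card = scorecard(inputs, hap, ctx_busco, ctx_kmer)
    print(
        f"assembly {name}: size_score {card.size_score:.3f}  n50 {card.n50:,}  "
        f"completeness {card.completeness:.3f}  haploidy {card.haploidy:.2f}"
    )
# Higher is better on every axis; B's oversized, poorly collapsed assembly
# loses on size, completeness and haploidy despite its extra sequence.
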