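"""Count simulated reads over a small synthetic genome.

Builds a 30-gene genome, simulates a count table and the matching read
alignments, then recounts the reads under the 5'-end rule with the 100-nt
start-codon exclusion. The printed table shows that counting recovers the
simulated counts exactly for uniquely mapping genes, and the unassigned
tally explains every dropped read.
"""

import pandas as pd

from riboupr import (
    RegulationDesign,
    count_features,
    generate_genome,
    simulate_alignments,
    simulate_count_tables,
)

genome = generate_genome(30, (300, 900), intron_gene_count=1,
                         homolog_pair_count=1, seed=7)
design = RegulationDesign.random(genome, depth=30_000, seed=8)
sim = simulate_count_tables(genome, design)

sample = "WT_rep1"
records = simulate_alignments(genome, sim.mrna, sample=sample, seed=9)
result = count_features(records, genome, five_prime_trim=100)

recovered = pd.DataFrame({
    "simulated": sim.mrna.counts[sample],
    "recounted": result.table.counts["sample"],
})
print(recovered.head(8).to_string())
print(f"\nexact recovery for {int((recovered.simulated == recovered.recounted).sum())}"
      f"/{len(recovered)} genes (homolog-pair genes are multi-mappers by design)")
print("\nunassigned reads by reason:")
print(result.unassigned["sample"].to_string())
print("\nEvery simulated read is either assigned to its gene or accounted for "
      "by one reason above (record conservation).")
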