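"""Map variant calls to flank-extended gene models.

Each gene span is widened by 2 kb per side; a call is assigned to every
extended gene containing it with a region label (upstream, UTRs, CDS,
intron, downstream), and CDS SNPs get a codon-level effect.
"""

import numpy as np

from poolsweep import (SeqConfig, SimConfig, assign_regions,
                       build_extended_index, call_snps, classify_coding,
                       evaluable_mask, simulate_experiment)

rng = np.random.default_rng(11)
sim = SimConfig(genome_length=50_000, n_arms=2, pop_size=500,
                generations=180)
res = simulate_experiment(sim, SeqConfig(mean_depth=20), rng,
                          polymorphic_site_density=5.0, n_genes=40,
                          n_targets=8, s=0.2)

mask, _ = evaluable_mask(res.table)
snps = call_snps(res.table, mask)
index = build_extended_index(res.genes, flank=2000,
                             arm_lengths=sim.arm_lengths)
assignments, intergenic = assign_regions(snps, index)

print(f"{len(snps)} SNPs -> {len(assignments)} gene assignments, "
      f"{len(intergenic)} intergenic")
for a in assignments:
    line = f"  {a.arm}:{a.pos} -> {a.gene_id} [{a.region}]"
    if a.region == "cds":
        call = next(c for c in snps if (c.arm, c.pos) == (a.arm, a.pos))
        eff = classify_coding(call, index.genes[a.gene_id].gene,
                              res.reference)
        line += f" {eff.ref_codon}->{eff.alt_codon} ({eff.effect})"
    print(line)
# A call can map to several overlapping extended genes; coding SNPs are
# classified as synonymous/nonsynonymous/nonsense by the genetic code.
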