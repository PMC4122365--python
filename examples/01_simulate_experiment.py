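"""Simulate a pooled evolve-and-resequence experiment.

Founds three populations from 27 isogenic lines, evolves one control
neutrally and two replicates under selection at planted loci, then pools
and sequences all three.  Prints the truth table for the planted sweeps.
"""

import numpy as np

from poolsweep import SeqConfig, SimConfig, simulate_experiment

rng = np.random.default_rng(11)
sim = SimConfig(genome_length=50_000, n_arms=2, pop_size=500,
                generations=180)
res = simulate_experiment(sim, SeqConfig(mean_depth=20), rng,
                          polymorphic_site_density=5.0,
                          n_targets=5, s=0.2)

print(f"{len(res.panel)} polymorphic sites on arms {res.panel.arms}")
print(f"{len(res.table)} pool-table rows for pools C1/H1/H2\n")
print("planted sweeps (true final frequencies):")
cols = ["arm", "pos", "p0", "freq_C1", "freq_H1", "freq_H2",
        "expected_callable"]
print(res.truth.query("selected")[cols].to_string(index=False))
# freq_H1/freq_H2 near 1.0 with freq_C1 low means the swept allele became a
# fixed difference; expected_callable marks sites the caller should find.
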