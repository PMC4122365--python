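# Methods

This note records the models, parameter choices and numerical conventions
behind `poolsweep`, and what the synthetic experiments do and do not show
about real pool-seq data.

## Experimental model

The simulator emulates a laboratory selection experiment on *Drosophila
melanogaster*-like genomes: populations founded from a balanced pool of
`n_founders = 27` isogenic lines, one control population evolving by drift
alone and two replicate populations sharing a set of selected loci, evolved
for `generations = 180`, then sampled as pools of `pool_males = 100` and
`pool_females = 100` adults and sequenced to a target depth per pool.

**Founder panel.** Polymorphic sites are placed uniformly at
`polymorphic_site_density` sites/kb (default 5/kb, a typical pool-seq SNP
density for *D. melanogaster*). Each site's minor allele is assigned to
`k ~ uniform{1..13}` of the 27 founder lines, spanning the founder
frequency spectrum p0 = k/27 from 0.037 to 0.48. A configurable fraction of
sites (default 0.1) are single-base insertions or deletions; each
supporting read records its strand so the indel typing rule (`*` vs `+`)
is exercised. Selection targets default to single-carrier sites (p0 =
1/27): a sweep starting from a rare variant is the regime the design
emulates, and it is also the only regime in which the control population
reliably stays below the 10% rarity bound over 180 generations (see
*Limitations*).

**Evolution.** By default sites evolve independently (free recombination,
`linkage="free"`): the per-site calling statistics do not depend on linkage,
and independence keeps the null analytically tractable. Each generation
applies the selection recursion p' = p(1+s)/(1+ps) and then binomial
resampling of the arm's gamete copy number: 2N on autosomes and 1.5N on
the X (equal sex ratio, males hemizygous). `pop_size` N defaults to 500
diploid individuals; the census size of the real selection chambers is not
knowable from the design, so N is exposed as a free parameter rather than
asserted. A per-generation census schedule (`pop_size_schedule`) emulates
reproductive bottlenecks. The opposite linkage extreme is available as
`linkage="blocks"`: no recombination within an arm, with the 27 founder
lineages drifting as units under multinomial resampling and lineage fitness
equal to the product of (1+s) over carried targets — useful for studying
clustering of hitchhiking calls. With `generations = 0` the founder
frequencies are returned exactly, which pins the neutral-expectation tests.

**Pooling.** Pools are drawn without replacement (hypergeometric in copy
space): 400 chromosome copies per autosomal site, 2·females + males = 300
on the X. The X copy-number asymmetry is modeled because chromosome-level
normalization of call counts is one of the reported outputs.

**Sequencing.** Per site and pool, depth ~ Poisson(`mean_depth`); each read
draws its allele from the pooled frequency and is flipped to a uniformly
chosen other base with probability `base_error` (default 0.002, an
Illumina-like post-filter error rate). Deletion-supporting reads contribute
no base call, so the base-count sum may fall short of depth; insertion
reads carry the reference base plus the insertion record. Quality fields
emulate Maq-style summaries: consensus base quality ~ round N(35, 5) and
best-read mapping quality ~ round N(50, 10), both clamped at 0. These
means/SDs deliberately straddle the 20/40 thresholds so that a realistic
fraction of loci (~60% under defaults; the real study reported ~50%) fails
the mask — passing tests therefore demonstrate behavior under partial
evaluability, not on ideal data.

## Calling conventions

- **Frequency denominator**: base frequencies divide by the site's A/C/G/T
  base-call sum, not raw depth, so gapped or masked reads do not dilute a
  pool's consensus; `freq_denominator="depth"` switches to raw depth.
- **Control consensus**: the majority base in C1, ties broken toward the
  reference and then by A<C<G<T order — conservative, since an ambiguous
  control suppresses calls.
- **H1/H2 identity** is recorded on every call but not required by default;
  discordant sites (different bases fixed in the two selected pools) are
  emitted with `h_identity=False` and both alleles stored.
- **Indels** use their own coverage rule (≥ 10 reads in both selected
  pools) rather than the three-pool SNP mask, mirroring the separate
  treatment of indels upstream; pass the mask explicitly to intersect.
  "Absent from the control" means ≤ `control_absence_max_reads` supporting
  reads (default 0). Count tables carry no insertion sequence, so
  insertion homopolymer flagging tests any single-base run touching the
  insertion point, while deletions test the run of the deleted base.
- **Reciprocal FDR**: a locus counts once even if both directions trigger.
  The default denominator is the number of called SNPs (recovering the
  published arithmetic, e.g. 1/2514 = 4.0e-4); `denominator="evaluable"`
  gives a per-locus rate, which is the form used in the null-calibration
  tests because the called-SNP denominator degenerates when no SNPs are
  called.

## Annotation and enrichment conventions

- Extended span = gene span ± `flank` (default 2000 bp), clipped to the
  arm. The region partition is painted with precedence CDS > UTR > intron,
  guaranteeing one label per position even for malformed models; UTRs are
  inferred as exon minus CDS when not annotated explicitly, 5'/3' by
  strand.
- A call contributes one polymorphism to **each** overlapping extended
  gene; µ's denominator is correspondingly the sum of per-gene extended
  lengths. `nonredundant_mu=True` switches to distinct loci over the union
  length.
- In the locus-level enrichment test, positions shared by two genes of the
  same set count once (set spans are merged before counting), and the
  position universe defaults to all positions in the universe's extended
  genes; `mask_loci` restricts it to evaluable positions. Raw p is the
  primary output; Benjamini–Hochberg q-values are reported alongside when
  several sets are tested.
- Arm-level call counts are normalized to density per kb and expressed
  relative to the X chromosome's density; region-level counts divide by
  the total loci of each region class and are expressed relative to the
  intron class. Both ratios are invariant to rescaling all lengths.

## Numerical choices

- Hypergeometric tails are computed through `scipy.stats.hypergeom.sf`
  (log-space internally); k = 0 returns exactly 1.0. The test suite pins
  agreement with exact integer pmf summation to relative error ≤ 1e-10
  over the full N ≤ 60 grid.
- All randomness flows through a single `numpy` Generator; the pipeline
  derives one substream per stage from the global seed, so every non-log
  output is byte-identical across reruns with the same config.
- Floats in TSV outputs are formatted to six significant digits to keep
  the byte-identity guarantee independent of float repr subtleties.

## Validation design

The simulation truth table stores each site's true final frequencies and
an `expected_callable` flag (the fixed/rare definition applied to true
frequencies). Three conventions in the validation suite deserve note:

- **Caller recall** is measured against planted targets that are both
  `expected_callable` and evaluable. Under the default drift regime
  (N = 500, 180 generations) the control population drifts above the 10%
  bound at roughly one in eight single-founder targets, and the quality
  model fails ~40% of loci; both are properties of the experiment, not of
  the caller, so they are excluded from the caller's denominator (they are
  visible separately in the pipeline report's confusion matrix).
- **Null calibration** of the reciprocal scan compares the observed
  reciprocal-locus rate with its analytic expectation given the truth
  table: per evaluable SNP site, the binomial probabilities of an observed
  fixed/rare discordance at the realized depths and true frequencies.
  Threshold statistics on ~15X counts are intrinsically smoothed near the
  0.9/0.1 boundaries, so the raw true-frequency rate is not the estimator's
  expectation — the read-sampling model is part of the quantity being
  estimated.
- **Enrichment calibration** uses genes whose extended spans are pairwise
  disjoint, because the per-position sampling null is exactly
  hypergeometric only when positions belong to a single gene set; with
  overlapping spans the planted excess leaks into neighboring sets.

## Limitations

- The default independent-site evolution ignores linkage; hitchhiking,
  background selection and sweep interference are absent, so clustering of
  calls around targets is not modeled (the `blocks` mode covers only the
  zero-recombination extreme).
- The quality model is parametric (normal emission), not learned from an
  aligner; it produces realistic pass/fail mixtures but no correlation
  between depth, base quality and mapping quality, which real alignments
  have.
- Pool construction assumes exactly equal founder contributions and a 1:1
  sex ratio; real pools have family structure and unequal contributions
  that inflate pool-seq variance.
- The paper-scale totals of the original study (thousands of calls over a
  120 Mb euchromatin genome, µ = 0.024/kb) require the deposited reads and
  a full annotation release; the package reproduces the *arithmetic* and
  the method's operating characteristics at desk scale, not those
  data-dependent totals.
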