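"""Synthetic evolve-and-resequence data generator.

Emulates the study design this package analyzes: populations founded from a
balanced pool of 27 isogenic lines, one control population drifting
neutrally and two replicate populations evolved under selection for ~180
generations, then pooled (100 males + 100 females) and sequenced as three
pool-seq samples with per-site depth, consensus base quality and best-read
mapping quality.

Sites evolve independently (free recombination) under a per-generation
Wright-Fisher update: the selection-weighted expected frequency
``p' = p(1+s)/(1+ps)`` followed by binomial sampling of the arm's gamete
copy number (2N on autosomes, 1.5N on the X with an equal sex ratio);
``linkage="blocks"`` switches to the zero-recombination extreme where the
founder lineages of an arm drift as units.  A
truth table records, per site, the founder frequency, the true final
frequency in each population, the selected flag, and whether the site
satisfies the fixed-difference calling definition on true frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .pool_io import BASES, POOLS, TABLE_COLUMNS, PoolSiteTable

DEFAULT_ARM_NAMES = ("X", "2L", "2R", "3L", "3R")

_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class SimConfig:
    """Experimental-evolution design parameters.

    ``selection_targets`` lists (arm, pos, s) loci shared by both selected
    replicates; the control always evolves with s = 0.  ``pop_size`` is the
    number of diploid individuals per population (sex ratio 1:1).
    """

    n_founders: int = 27
    genome_length: int = 100_000  # bp per chromosome arm
    n_arms: int = 1
    arm_names: tuple[str, ...] | None = None
    pop_size: int = 500
    generations: int = 180
    selection_targets: tuple[tuple[str, int, float], ...] = ()
    pool_males: int = 100
    pool_females: int = 100
    #: optional per-generation census sizes (length = generations), e.g. to
    #: emulate a reproductive bottleneck; the final entry is the population
    #: the pools are drawn from
    pop_size_schedule: tuple[int, ...] | None = None
    #: "free" = independent-site evolution (free recombination);
    #: "blocks" = no recombination within an arm (founder-lineage dynamics)
    linkage: str = "free"
    seed: int | None = None

    def __post_init__(self):
        if self.n_founders < 1:
            raise ValueError("n_founders must be positive")
        if self.n_arms < 1:
            raise ValueError("n_arms must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.pool_males + self.pool_females > self.pop_size:
            raise ValueError("pool larger than population")
        for arm, pos, s in self.selection_targets:
            if not math.isfinite(s):
                raise ValueError(f"non-finite selection coefficient at "
                                 f"{arm}:{pos}")
            if s <= -1:
                raise ValueError(f"s must be > -1 at {arm}:{pos}")
        if self.arm_names is not None and len(self.arm_names) != self.n_arms:
            raise ValueError("arm_names length must equal n_arms")
        if self.pop_size_schedule is not None:
            if len(self.pop_size_schedule) != self.generations:
                raise ValueError(
                    "pop_size_schedule length must equal generations")
            if any(n < 2 for n in self.pop_size_schedule):
                raise ValueError("scheduled pop sizes must be >= 2")
        if self.linkage not in ("free", "blocks"):
            raise ValueError("linkage must be 'free' or 'blocks'")

    @property
    def arms(self) -> tuple[str, ...]:
        if self.arm_names is not None:
            return tuple(self.arm_names)
        return DEFAULT_ARM_NAMES[: self.n_arms]

    @property
    def arm_lengths(self) -> dict[str, int]:
        return {arm: self.genome_length for arm in self.arms}


@dataclass(frozen=True)
class SeqConfig:
    """Pool-seq emulation parameters (Maq-style quality fields).

    Qualities are clamped rounds of normal draws; the defaults produce a
    realistic mixture of passing and failing loci around the 20/40
    evaluability thresholds.
    """

    mean_depth: float = 20.0
    base_error: float = 0.002
    baseq_mean: float = 35.0
    baseq_sd: float = 5.0
    bestq_mean: float = 50.0
    bestq_sd: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.base_error < 0.5):
            raise ValueError("base_error must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# Founders

@dataclass
class FounderPanel:
    """Polymorphic sites segregating among the founder lines.

    ``sites`` columns: arm, pos (1-based), ref, kind ("snp"/"ins"/"del"),
    alt (alternate base for SNPs, inserted base for insertions, deleted base
    for deletions), k (carrier founders), p0 (= k / n_founders).
    ``haplotypes`` is the n_founders x n_sites carrier matrix.
    """

    arms: tuple[str, ...]
    arm_lengths: dict[str, int]
    reference: dict[str, str]
    sites: pd.DataFrame
    haplotypes: np.ndarray
    n_founders: int

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def p0(self) -> np.ndarray:
        return self.sites["p0"].to_numpy()

    @property
    def arm_is_x(self) -> np.ndarray:
        return (self.sites["arm"] == "X").to_numpy()


def _random_reference(arms: Iterable[str], length: int,
                      rng: np.random.Generator) -> dict[str, str]:
    return {
        arm: "".join(np.array(list(BASES))[rng.integers(0, 4, length)])
        for arm in arms
    }


def generate_founders(sim_config: SimConfig, polymorphic_site_density: float,
                      rng: np.random.Generator,
                      reference: Mapping[str, str] | None = None,
                      indel_fraction: float = 0.1) -> FounderPanel:
    """Draw polymorphic sites and assign each site's minor allele to
    k ~ uniform{1..13} founder lines.

    ``polymorphic_site_density`` is in sites per kb.  The reference carries
    the ancestral allele at every site; a configurable fraction of sites are
    single-base insertions/deletions.
    """
    if polymorphic_site_density < 0:
        raise ValueError("density must be >= 0")
    if sim_config.genome_length == 0:
        raise ValueError("empty genome")
    arms = sim_config.arms
    if reference is None:
        reference = _random_reference(arms, sim_config.genome_length, rng)
    else:
        reference = dict(reference)
    k_max = min(13, sim_config.n_founders - 1) if sim_config.n_founders > 1 else 1
    rows = []
    for arm in sorted(arms):
        length = len(reference[arm])
        n_sites = int(round(polymorphic_site_density * length / 1000))
        n_sites = min(n_sites, max(length - 2, 0))
        if n_sites == 0:
            continue
        positions = np.sort(rng.choice(
            np.arange(2, length), size=n_sites, replace=False))
        kinds = np.where(rng.random(n_sites) < indel_fraction, "indel", "snp")
        for pos, kind in zip(positions, kinds):
            ref_base = reference[arm][pos - 1]
            if kind == "snp":
                others = [b for b in BASES if b != ref_base]
                alt = others[rng.integers(0, 3)]
                k = "snp"
            else:
                k = "del" if rng.random() < 0.5 else "ins"
                alt = (ref_base if k == "del"
                       else BASES[rng.integers(0, 4)])
            rows.append({"arm": arm, "pos": int(pos), "ref": ref_base,
                         "kind": k if kind == "indel" else "snp",
                         "alt": alt,
                         "k": int(rng.integers(1, k_max + 1))})
    sites = pd.DataFrame(
        rows, columns=["arm", "pos", "ref", "kind", "alt", "k"])
    sites = sites.sort_values(["arm", "pos"], kind="stable").reset_index(drop=True)
    sites["p0"] = sites["k"] / sim_config.n_founders
    haplotypes = np.zeros((sim_config.n_founders, len(sites)), dtype=bool)
    for j, k in enumerate(sites["k"]):
        carriers = rng.choice(sim_config.n_founders, size=int(k), replace=False)
        haplotypes[carriers, j] = True
    return FounderPanel(arms=arms, arm_lengths=dict(sim_config.arm_lengths),
                        reference=reference, sites=sites,
                        haplotypes=haplotypes,
                        n_founders=sim_config.n_founders)


def select_sweep_targets(panel: FounderPanel, n_targets: int, s: float,
                         rng: np.random.Generator,
                         single_carrier: bool = True,
                         kinds: tuple[str, ...] = ("snp",)
                         ) -> tuple[tuple[str, int, float], ...]:
    """Pick panel sites as selection targets, by default preferring SNP
    sites whose selected allele segregates in a single founder line (a
    sweep from rare; sites with more carriers fill in only when too few
    single-carrier sites exist).  ``kinds`` may include "ins"/"del" to
    plant indel sweeps."""
    sites = panel.sites
    eligible = sites.index[sites["kind"].isin(kinds)].to_numpy()
    if len(eligible) < n_targets:
        raise ValueError(
            f"only {len(eligible)} eligible sites for {n_targets} targets")
    if single_carrier:
        ks = sites.loc[eligible, "k"].to_numpy()
        order = np.lexsort((rng.random(len(eligible)), ks))
        chosen = eligible[order][:n_targets]
    else:
        chosen = rng.choice(eligible, size=n_targets, replace=False)
    chosen.sort()
    return tuple(
        (str(sites.at[i, "arm"]), int(sites.at[i, "pos"]), float(s))
        for i in chosen
    )


# ---------------------------------------------------------------------------
# Evolution

@dataclass
class Population:
    """Final allele-frequency state of one population."""

    name: str
    freqs: np.ndarray       # alternate-allele frequency per site
    copies: np.ndarray      # gamete copy number per site (arm-aware)
    pop_size: int
    arm_is_x: np.ndarray


def _copies_per_site(arm_is_x: np.ndarray, n_individuals: int,
                     males: int | None = None,
                     females: int | None = None) -> np.ndarray:
    if males is None:
        males = n_individuals // 2
        females = n_individuals - males
    aut = 2 * (males + females)
    x = 2 * females + males
    return np.where(arm_is_x, x, aut).astype(np.int64)


def wright_fisher(p0: np.ndarray, copies: np.ndarray, s: np.ndarray,
                  generations: int, rng: np.random.Generator) -> np.ndarray:
    """Per-site Wright-Fisher trajectory endpoint.

    Each generation applies the selection recursion p' = p(1+s)/(1+ps) and
    resamples the gamete pool binomially.  ``copies`` is either a per-site
    vector (constant census) or a (generations, n_sites) array for a
    per-generation schedule such as a bottleneck.  With
    ``generations == 0`` the founder frequencies are returned exactly.
    """
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite selection coefficient")
    if np.any(s <= -1):
        raise ValueError("selection coefficient must be > -1")
    copies = np.asarray(copies)
    p = np.asarray(p0, dtype=float).copy()
    for g in range(generations):
        c = copies[g] if copies.ndim == 2 else copies
        p = p * (1 + s) / (1 + p * s)
        p = rng.binomial(c, p) / c
    return p


def _wright_fisher_blocks(panel: FounderPanel, copies: np.ndarray,
                          s: np.ndarray, generations: int,
                          rng: np.random.Generator) -> np.ndarray:
    """No-recombination variant: founder lineages drift as units per arm.

    Each arm carries ``n_founders`` lineage frequencies (balanced start);
    a lineage's fitness is the product of (1+s) over the selected sites it
    carries, and lineage counts are multinomially resampled each
    generation.  Site frequencies are sums over carrier lineages.
    """
    sites = panel.sites
    arms = sites["arm"].to_numpy()
    freqs = np.empty(len(sites))
    for arm in np.unique(arms):
        idx = np.nonzero(arms == arm)[0]
        hap = panel.haplotypes[:, idx]  # n_founders x n_arm_sites
        w = np.prod(np.where(hap, 1 + s[idx], 1.0), axis=1)
        x = np.full(panel.n_founders, 1.0 / panel.n_founders)
        arm_copies = copies[:, idx[0]] if copies.ndim == 2 else \
            np.full(generations, copies[idx[0]])
        for g in range(generations):
            xw = x * w
            counts = rng.multinomial(arm_copies[g], xw / xw.sum())
            x = counts / arm_copies[g]
        freqs[idx] = hap.T @ x
    return freqs


def deterministic_selection(p0: float, s: float, generations: int) -> float:
    """Infinite-population limit of the selection recursion (test oracle)."""
    p = p0
    for _ in range(generations):
        p = p * (1 + s) / (1 + p * s)
    return p


def expected_callable(f_c1: np.ndarray, f_h1: np.ndarray, f_h2: np.ndarray,
                      fix_threshold: float = 0.90,
                      rare_threshold: float = 0.10) -> np.ndarray:
    """The fixed-difference definition applied to true frequencies."""
    return ((f_h1 >= fix_threshold) & (f_h2 >= fix_threshold)
            & (f_c1 <= rare_threshold))


def evolve_replicates(panel: FounderPanel, sim_config: SimConfig,
                      rng: np.random.Generator,
                      targets: Sequence[tuple[str, int, float]] | None = None
                      ) -> tuple[dict[str, Population], pd.DataFrame]:
    """Evolve C1 (neutral) and H1/H2 (shared selection targets) independently
    from the founder-balanced starting pool; return populations + truth table.
    """
    if sim_config.pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if targets is None:
        targets = sim_config.selection_targets
    sites = panel.sites
    n = len(sites)
    arm_is_x = panel.arm_is_x
    if sim_config.pop_size_schedule is not None:
        copies = np.stack([_copies_per_site(arm_is_x, n_g)
                           for n_g in sim_config.pop_size_schedule]) \
            if sim_config.generations else _copies_per_site(
                arm_is_x, sim_config.pop_size)
        final_n = (sim_config.pop_size_schedule[-1]
                   if sim_config.pop_size_schedule else sim_config.pop_size)
    else:
        copies = _copies_per_site(arm_is_x, sim_config.pop_size)
        final_n = sim_config.pop_size
    final_copies = _copies_per_site(arm_is_x, final_n)
    s_sel = np.zeros(n)
    key_to_row = {(a, p): i for i, (a, p) in
                  enumerate(zip(sites["arm"], sites["pos"]))}
    selected = np.zeros(n, dtype=bool)
    for arm, pos, s in targets:
        if not math.isfinite(s):
            raise ValueError(f"non-finite s at {arm}:{pos}")
        if s <= -1:
            raise ValueError(f"s must be > -1 at {arm}:{pos}")
        try:
            i = key_to_row[(arm, int(pos))]
        except KeyError:
            raise ValueError(f"selection target {arm}:{pos} is not a panel "
                             f"site") from None
        s_sel[i] = s
        selected[i] = True
    p0 = panel.p0
    zero = np.zeros(n)
    pops = {}
    for name, s_vec in (("C1", zero), ("H1", s_sel), ("H2", s_sel)):
        if sim_config.linkage == "blocks":
            freqs = _wright_fisher_blocks(panel, copies, s_vec,
                                          sim_config.generations, rng)
        else:
            freqs = wright_fisher(p0, copies, s_vec,
                                  sim_config.generations, rng)
        pops[name] = Population(name=name, freqs=freqs, copies=final_copies,
                                pop_size=final_n, arm_is_x=arm_is_x)
    truth = sites[["arm", "pos", "ref", "kind", "alt", "p0"]].copy()
    truth["freq_C1"] = pops["C1"].freqs
    truth["freq_H1"] = pops["H1"].freqs
    truth["freq_H2"] = pops["H2"].freqs
    truth["selected"] = selected
    truth["expected_callable"] = expected_callable(
        truth["freq_C1"].to_numpy(), truth["freq_H1"].to_numpy(),
        truth["freq_H2"].to_numpy())
    return pops, truth


# ---------------------------------------------------------------------------
# Pooling and sequencing

def sample_pool(population: Population, pool_males: int, pool_females: int,
                rng: np.random.Generator) -> np.ndarray:
    """Pool allele frequencies from individuals sampled without replacement.

    Chromosome copy number is 2 per individual on autosomes and
    2*females + males on the X (males hemizygous).
    """
    if pool_males + pool_females > population.pop_size:
        raise ValueError("pool larger than population")
    pool_copies = _copies_per_site(population.arm_is_x, 0,
                                   males=pool_males, females=pool_females)
    pop_counts = np.rint(population.freqs * population.copies).astype(np.int64)
    good = pop_counts
    bad = population.copies - pop_counts
    drawn = rng.hypergeometric(np.maximum(good, 0), np.maximum(bad, 0),
                               np.minimum(pool_copies, population.copies))
    return drawn / pool_copies


def sequence_pool(pool_freqs: np.ndarray, seq_config: SeqConfig,
                  panel: FounderPanel, rng: np.random.Generator
                  ) -> dict[str, np.ndarray]:
    """Emulate pool-seq read counts for one pool over all panel sites.

    Depth is Poisson; each read draws its allele from the pool frequency;
    base-call errors flip a read's base to a uniformly chosen other base
    with probability ``base_error``.  Deletion-supporting reads contribute
    no base call (the base-count sum then falls short of depth);
    insertion-supporting reads carry the reference base plus the insertion.
    Returns the per-pool column block of the pool table.
    """
    n = len(panel)
    sites = panel.sites
    ref_idx = sites["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    alt_idx = sites["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    kind = sites["kind"].to_numpy()
    depth = rng.poisson(seq_config.mean_depth, n)
    alt_reads = rng.binomial(depth, pool_freqs)
    ref_reads = depth - alt_reads
    counts = np.zeros((n, 4), dtype=np.int64)
    out = {
        "depth": depth,
        "del": np.zeros(n, dtype=np.int64),
        "ins": np.zeros(n, dtype=np.int64),
        "del_fwd": np.zeros(n, dtype=np.int64),
        "del_rev": np.zeros(n, dtype=np.int64),
        "ins_fwd": np.zeros(n, dtype=np.int64),
        "ins_rev": np.zeros(n, dtype=np.int64),
    }
    is_del = kind == "del"
    is_ins = kind == "ins"
    # base-carrying reads: all except deletion-supporting ones
    base_ref = ref_reads + np.where(is_ins, alt_reads, 0)
    base_alt = np.where(kind == "snp", alt_reads, 0)
    counts[np.arange(n), ref_idx] += base_ref
    snp_rows = np.nonzero(base_alt > 0)[0]
    counts[snp_rows, alt_idx[snp_rows]] += base_alt[snp_rows]
    # indel support and strand split
    for flag, name in ((is_del, "del"), (is_ins, "ins")):
        rows = np.nonzero(flag)[0]
        sup = alt_reads[rows]
        fwd = rng.binomial(sup, 0.5)
        out[name][rows] = sup
        out[f"{name}_fwd"][rows] = fwd
        out[f"{name}_rev"][rows] = sup - fwd
    # sequencing errors: flip each base call with probability base_error
    if seq_config.base_error > 0:
        n_err = rng.binomial(counts, seq_config.base_error)
        err_rows, err_cols = np.nonzero(n_err)
        for i, b in zip(err_rows, err_cols):
            others = [j for j in range(4) if j != b]
            dest = rng.choice(others, size=n_err[i, b])
            counts[i, b] -= n_err[i, b]
            for d in dest:
                counts[i, d] += 1
    for j, b in enumerate(BASES):
        out[b] = counts[:, j]
    out["baseq"] = np.clip(np.rint(rng.normal(
        seq_config.baseq_mean, seq_config.baseq_sd, n)), 0, None).astype(np.int64)
    out["bestq"] = np.clip(np.rint(rng.normal(
        seq_config.bestq_mean, seq_config.bestq_sd, n)), 0, None).astype(np.int64)
    return out


def build_pool_table(panel: FounderPanel,
                     pool_blocks: Mapping[str, Mapping[str, np.ndarray]]
                     ) -> PoolSiteTable:
    """Assemble the three per-pool column blocks into a PoolSiteTable."""
    data: dict[str, object] = {
        "arm": panel.sites["arm"].to_numpy(),
        "pos": panel.sites["pos"].to_numpy(),
        "ref": panel.sites["ref"].to_numpy(),
    }
    for pool in POOLS:
        block = pool_blocks[pool]
        for suffix in ("depth", "A", "C", "G", "T", "del", "ins",
                       "del_fwd", "del_rev", "ins_fwd", "ins_rev",
                       "baseq", "bestq"):
            data[f"{pool}_{suffix}"] = block[suffix]
    return PoolSiteTable(pd.DataFrame(data, columns=TABLE_COLUMNS))


# ---------------------------------------------------------------------------
# Annotation substrate

def generate_annotation(arm_lengths: Mapping[str, int], n_genes: int,
                        rng: np.random.Generator,
                        n_pathways: int = 2,
                        reference: Mapping[str, str] | None = None
                        ) -> tuple[dict[str, str], list[GeneModel],
                                   dict[str, set[str]]]:
    """Generate non-degenerate gene models, a matching reference, and
    pathway gene sets.

    Every gene has a 5'UTR exon portion, two CDS exons separated by an
    intron, and a 3'UTR; the CDS starts with ATG, contains no internal stop
    codon and ends with a stop.  The reference sequence is rewritten inside
    CDS segments so the models translate cleanly.  Genes are packed into
    evenly sized slots per arm; an arm too short for its share raises
    "infeasible packing".
    """
    if n_pathways < 2:
        raise ValueError("need at least 2 pathway sets")
    arms = sorted(arm_lengths)
    if reference is None:
        reference = {
            arm: "".join(np.array(list(BASES))[
                rng.integers(0, 4, arm_lengths[arm])])
            for arm in arms
        }
    ref_arrays = {arm: list(reference[arm]) for arm in arms}
    genes: list[GeneModel] = []
    per_arm = [n_genes // len(arms) + (1 if i < n_genes % len(arms) else 0)
               for i in range(len(arms))]
    gid = 0
    for arm, count in zip(arms, per_arm):
        if count == 0:
            continue
        slot = arm_lengths[arm] // count
        for j in range(count):
            gid += 1
            n_codons = int(rng.integers(60, 200))
            cds_len = 3 * n_codons
            utr5 = int(rng.integers(60, 150))
            utr3 = int(rng.integers(60, 200))
            intron = int(rng.integers(60, 120))
            cut = int(rng.integers(30, cds_len - 30))
            glen = utr5 + cds_len + intron + utr3
            if glen + 20 > slot:
                raise ValueError(
                    f"infeasible packing: gene of {glen} bp does not fit "
                    f"slot of {slot} bp on arm {arm}")
            jitter = int(rng.integers(1, slot - glen - 10))
            gstart = j * slot + jitter + 1
            gend = gstart + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            phase2 = (3 - cut % 3) % 3
            if strand == "+":
                cds1 = (gstart + utr5, gstart + utr5 + cut - 1, 0)
                cds2 = (cds1[1] + intron + 1,
                        cds1[1] + intron + (cds_len - cut), phase2)
                exons = ((gstart, cds1[1]), (cds2[0], gend))
            else:
                # genome order: utr3, cdsB(len cds_len-cut), intron,
                # cdsA(len cut), utr5; transcription runs right to left
                cdsB = (gstart + utr3, gstart + utr3 + (cds_len - cut) - 1,
                        phase2)
                cdsA = (cdsB[1] + intron + 1, cdsB[1] + intron + cut, 0)
                cds1, cds2 = cdsB, cdsA
                exons = ((gstart, cdsB[1]), (cdsA[0], gend))
            interior = rng.choice(len(_NONSTOP_CODONS), n_codons - 2)
            cds_seq = ("ATG"
                       + "".join(_NONSTOP_CODONS[i] for i in interior)
                       + _STOPS[rng.integers(0, 3)])
            if strand == "+":
                pieces = (cds_seq[:cut], cds_seq[cut:])
            else:
                rc = _revcomp(cds_seq)
                pieces = (rc[: cds_len - cut], rc[cds_len - cut:])
            for (s, e, _ph), piece in zip((cds1, cds2), pieces):
                ref_arrays[arm][s - 1: e] = list(piece)
            genes.append(GeneModel(
                gene_id=f"gene{gid:04d}", arm=arm, strand=strand,
                start=gstart, end=gend, exons=exons, cds=(cds1, cds2)))
    reference_out = {arm: "".join(ref_arrays[arm]) for arm in arms}
    pathway_sets: dict[str, set[str]] = {
        f"pathway_{i + 1:02d}": set() for i in range(n_pathways)}
    for i, g in enumerate(genes):
        pathway_sets[f"pathway_{i % n_pathways + 1:02d}"].add(g.gene_id)
    return reference_out, genes, pathway_sets


# ---------------------------------------------------------------------------
# End-to-end experiment

@dataclass
class SimResult:
    reference: dict[str, str]
    genes: list[GeneModel]
    pathway_sets: dict[str, set[str]]
    panel: FounderPanel
    populations: dict[str, Population]
    truth: pd.DataFrame
    table: PoolSiteTable
    targets: tuple[tuple[str, int, float], ...] = field(default_factory=tuple)


def simulate_experiment(sim_config: SimConfig, seq_config: SeqConfig,
                        rng: np.random.Generator,
                        polymorphic_site_density: float = 5.0,
                        n_genes: int = 0, n_pathways: int = 2,
                        n_targets: int = 0, s: float = 0.0,
                        n_indel_targets: int = 0,
                        indel_fraction: float = 0.1) -> SimResult:
    """Run the whole generator: annotation, founders, evolution, pooling and
    sequencing, returning every artifact plus the truth table."""
    if n_genes > 0:
        reference, genes, pathway_sets = generate_annotation(
            sim_config.arm_lengths, n_genes, rng, n_pathways=n_pathways)
    else:
        reference, genes, pathway_sets = None, [], {}
    panel = generate_founders(sim_config, polymorphic_site_density, rng,
                              reference=reference,
                              indel_fraction=indel_fraction)
    targets = sim_config.selection_targets
    if not targets and (n_targets > 0 or n_indel_targets > 0):
        chosen: tuple[tuple[str, int, float], ...] = ()
        if n_targets > 0:
            chosen += select_sweep_targets(panel, n_targets, s, rng)
        if n_indel_targets > 0:
            chosen += select_sweep_targets(panel, n_indel_targets, s, rng,
                                           kinds=("ins", "del"))
        targets = chosen
    pops, truth = evolve_replicates(panel, sim_config, rng, targets=targets)
    blocks = {}
    for name in POOLS:
        pooled = sample_pool(pops[name], sim_config.pool_males,
                             sim_config.pool_females, rng)
        blocks[name] = sequence_pool(pooled, seq_config, panel, rng)
    table = build_pool_table(panel, blocks)
    return SimResult(reference=panel.reference, genes=genes,
                     pathway_sets=pathway_sets, panel=panel,
                     populations=pops, truth=truth, table=table,
                     targets=tuple(targets))
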