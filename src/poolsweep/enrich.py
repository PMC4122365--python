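"""Polymorphism-density statistics and hypergeometric set enrichment.

The genome-wide expectation µ is the number of polymorphisms mapped to
extended genes divided by the total extended-gene length in kb; per-gene
densities are expressed as multiples of µ so that long genes are not
mistaken for enriched ones.  Enrichment is tested with the upper-tail
hypergeometric probability P(X >= k), either at locus level (positions
within extended-gene spans) or at gene level (overlap of a polymorphic gene
set with a target gene set drawn from a common universe).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import ExtendedGeneIndex, RegionAssignment


@dataclass(frozen=True)
class DensityStats:
    """Genome-wide µ plus per-gene polymorphism densities."""

    mu: float  # polymorphisms per kb of extended gene
    per_gene: pd.DataFrame  # gene_id, count, ext_kb, density, multiple

    def genes_at_multiple(self, multiple: float) -> list[str]:
        sel = self.per_gene["multiple"] >= multiple
        return self.per_gene.loc[sel, "gene_id"].tolist()

    def genes_at_density(self, per_kb: float) -> list[str]:
        sel = self.per_gene["density"] >= per_kb
        return self.per_gene.loc[sel, "gene_id"].tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    N: int  # population size
    K: int  # successes in population
    n: int  # draws
    k: int  # observed successes
    p_upper: float
    mode: str  # "locus" or "gene"


def compute_density_stats(assignments: Sequence[RegionAssignment],
                          index: ExtendedGeneIndex,
                          nonredundant_mu: bool = False) -> DensityStats:
    """Per-gene polymorphism counts, densities and multiples of µ.

    Each (call, gene) assignment contributes one polymorphism to that gene's
    count, so a call inside two overlapping extended genes counts once in
    each — µ's denominator is correspondingly the sum of per-gene extended
    lengths.  ``nonredundant_mu`` switches µ to distinct call loci over the
    union length of all extended spans.
    """
    if not index.genes:
        raise ValueError("empty gene index: zero total extended length")
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.gene_id] = counts.get(a.gene_id, 0) + 1
    rows = []
    for gid in sorted(index.genes):
        eg = index.genes[gid]
        kb = eg.ext_length / 1000
        c = counts.get(gid, 0)
        rows.append({"gene_id": gid, "count": c, "ext_kb": kb,
                     "density": c / kb})
    per_gene = pd.DataFrame(rows)
    total_kb = per_gene["ext_kb"].sum()
    if total_kb <= 0:
        raise ValueError("zero total extended-gene length")
    if nonredundant_mu:
        distinct = len({(a.arm, a.pos) for a in assignments})
        union_kb = _union_length(index, set(index.genes)) / 1000
        mu = distinct / union_kb
    else:
        mu = per_gene["count"].sum() / total_kb
    per_gene["multiple"] = per_gene["density"] / mu if mu > 0 else 0.0
    return DensityStats(mu=float(mu), per_gene=per_gene)


def hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space.

    Accepts scalars or equally shaped arrays; bounds are validated and
    k = 0 returns exactly 1.0.
    """
    N_, K_, n_, k_ = (np.asarray(x) for x in (N, K, n, k))
    if not (np.all(0 <= K_) and np.all(K_ <= N_) and np.all(0 <= n_)
            and np.all(n_ <= N_)):
        raise ValueError(f"invalid hypergeometric bounds N={N}, K={K}, n={n}")
    if not (np.all(0 <= k_) and np.all(k_ <= np.minimum(K_, n_))):
        raise ValueError(f"k={k} outside [0, min(K, n)]")
    p = np.where(k_ == 0, 1.0, stats.hypergeom.sf(k_ - 1, N_, K_, n_))
    if np.isscalar(k) or k_.ndim == 0:
        return float(p)
    return p


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals."""
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _gene_set_spans(index: ExtendedGeneIndex, genes: Iterable[str]
                    ) -> dict[str, list[tuple[int, int]]]:
    per_arm: dict[str, list[tuple[int, int]]] = {}
    for gid in genes:
        eg = index.genes[gid]
        per_arm.setdefault(eg.gene.arm, []).append((eg.ext_start, eg.ext_end))
    return {arm: _merge_intervals(ivs) for arm, ivs in per_arm.items()}


def _union_length(index: ExtendedGeneIndex, genes: Iterable[str]) -> int:
    spans = _gene_set_spans(index, genes)
    return sum(e - s + 1 for ivs in spans.values() for s, e in ivs)


def _loci_in_spans(loci: Iterable[tuple[str, int]],
                   spans: Mapping[str, list[tuple[int, int]]]) -> int:
    count = 0
    by_arm: dict[str, np.ndarray] = {
        arm: np.array(ivs).reshape(-1, 2) for arm, ivs in spans.items()}
    for arm, pos in loci:
        ivs = by_arm.get(arm)
        if ivs is None:
            continue
        i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        if i >= 0 and pos <= ivs[i, 1]:
            count += 1
    return count


def locus_enrichment(calls: Sequence, index: ExtendedGeneIndex,
                     pathway_sets: Mapping[str, set[str]],
                     universe: str | set[str], target: str,
                     mask_loci: set[tuple[str, int]] | None = None
                     ) -> EnrichmentResult:
    """Locus-level enrichment of polymorphisms in a target gene set.

    N counts the positions within the universe genes' extended spans
    (positions shared by overlapping genes count once), K those within the
    target set, n the distinct polymorphic loci among the N, and k among the
    K.  ``mask_loci`` restricts the position universe to evaluable loci.
    """
    universe_genes = (pathway_sets[universe] if isinstance(universe, str)
                      else set(universe))
    target_genes = pathway_sets[target]
    if not target_genes:
        raise ValueError(f"empty target set {target!r}")
    if not target_genes <= universe_genes:
        raise ValueError(f"target set {target!r} not within the universe")
    missing = universe_genes - set(index.genes)
    if missing:
        raise ValueError(f"universe genes absent from index: "
                         f"{sorted(missing)[:5]}")
    uni_spans = _gene_set_spans(index, universe_genes)
    tgt_spans = _gene_set_spans(index, target_genes)
    if mask_loci is None:
        N = sum(e - s + 1 for ivs in uni_spans.values() for s, e in ivs)
        K = sum(e - s + 1 for ivs in tgt_spans.values() for s, e in ivs)
    else:
        N = _loci_in_spans(mask_loci, uni_spans)
        K = _loci_in_spans(mask_loci, tgt_spans)
    loci = sorted({(c.arm, c.pos) for c in calls})
    n = _loci_in_spans(loci, uni_spans)
    k = _loci_in_spans(loci, tgt_spans)
    return EnrichmentResult(N=N, K=K, n=n, k=k,
                            p_upper=hypergeom_upper_tail(N, K, n, k),
                            mode="locus")


def gene_overlap_enrichment(polymorphic_genes: set[str],
                            target_gene_set: set[str],
                            universe: int | set[str]) -> EnrichmentResult:
    """Gene-level overlap enrichment between a polymorphic gene set and a
    target set, against a universe given as a gene count or explicit set."""
    if isinstance(universe, int):
        N = universe
        if max(len(polymorphic_genes), len(target_gene_set)) > N:
            raise ValueError("sets larger than the declared universe")
    else:
        if not (polymorphic_genes <= universe and target_gene_set <= universe):
            raise ValueError("sets must be subsets of the universe")
        N = len(universe)
    K = len(target_gene_set)
    n = len(polymorphic_genes)
    k = len(polymorphic_genes & target_gene_set)
    return EnrichmentResult(N=N, K=K, n=n, k=k,
                            p_upper=hypergeom_upper_tail(N, K, n, k),
                            mode="gene")


def enrich_all(calls: Sequence, index: ExtendedGeneIndex,
               pathway_sets: Mapping[str, set[str]],
               universe: str | set[str] | None = None,
               mask_loci: set[tuple[str, int]] | None = None) -> pd.DataFrame:
    """Locus-level enrichment for every pathway set, with BH correction.

    The universe defaults to the union of all pathway sets.  Raw p stays the
    primary output; the BH q-value is reported alongside.
    """
    if universe is None:
        universe = set().union(*pathway_sets.values())
    rows = []
    for name in sorted(pathway_sets):
        r = locus_enrichment(calls, index, pathway_sets, universe, name,
                             mask_loci=mask_loci)
        rows.append({"set": name, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                     "p": r.p_upper})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_bh"] = stats.false_discovery_control(df["p"], method="bh")
    return df
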