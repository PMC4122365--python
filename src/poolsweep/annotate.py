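"""Variant-to-gene mapping over extended gene models.

A gene's *extended* span is its annotated span widened by a fixed flank
(default 2 kb) on each side, clipped to the chromosome arm.  Within one
extended gene every position carries exactly one region label from
``{upstream, utr5, cds, intron, utr3, downstream}``; a variant is assigned to
every gene whose extended span contains it.  Coding SNPs are classified by
strand-aware codon substitution under the standard genetic code.

Coordinates on :class:`GeneModel` and in files are 1-based inclusive; the
partition is built on a 0-based scratch array internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

#: Region labels in 5'→3' order along a gene's own strand.
REGIONS = ("upstream", "utr5", "cds", "intron", "utr3", "downstream")

DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class GeneModel:
    """One gene model: span, exons and CDS segments (1-based inclusive)."""

    gene_id: str
    arm: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...]  # (start, end, phase) in genome order

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


@dataclass(frozen=True)
class ExtendedGene:
    gene: GeneModel
    ext_start: int
    ext_end: int
    #: contiguous (start, end, label) blocks tiling [ext_start, ext_end]
    blocks: tuple[tuple[int, int, str], ...]

    @property
    def ext_length(self) -> int:
        return self.ext_end - self.ext_start + 1

    def region_at(self, pos: int) -> str | None:
        if not (self.ext_start <= pos <= self.ext_end):
            return None
        lo, hi = 0, len(self.blocks) - 1
        while lo <= hi:
            mid = (lo + hi) // 2
            s, e, label = self.blocks[mid]
            if pos < s:
                hi = mid - 1
            elif pos > e:
                lo = mid + 1
            else:
                return label
        raise AssertionError("partition does not tile the extended span")


@dataclass
class ExtendedGeneIndex:
    """Extended gene models plus an interval tree per arm for lookup."""

    genes: dict[str, ExtendedGene]
    flank: int
    arm_lengths: dict[str, int]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for eg in self.genes.values():
            arm = eg.gene.arm
            tree = self._trees.setdefault(arm, IntervalTree())
            # interval tree is half-open
            tree.addi(eg.ext_start, eg.ext_end + 1, eg.gene.gene_id)

    def overlapping(self, arm: str, pos: int) -> list[ExtendedGene]:
        tree = self._trees.get(arm)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(pos))
        return [self.genes[g] for g in hits]

    def region_totals(self) -> dict[str, int]:
        """Total bp per region class summed over all extended genes."""
        totals = {r: 0 for r in REGIONS}
        for eg in self.genes.values():
            for s, e, label in eg.blocks:
                totals[label] += e - s + 1
        return totals


@dataclass(frozen=True)
class RegionAssignment:
    arm: str
    pos: int
    gene_id: str
    region: str
    multi_gene: bool


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str
    codon_index: int  # 0-based along the coding sequence
    ref_codon: str
    alt_codon: str
    effect: str  # synonymous | nonsynonymous | nonsense | lost-stop | non-coding


def _partition_gene(gene: GeneModel, ext_start: int, ext_end: int
                    ) -> tuple[tuple[int, int, str], ...]:
    """Label every position of the extended span, then compress to blocks.

    Painting order implements the precedence CDS > UTR > intron so that even
    a malformed model yields a single label per position.
    """
    n = ext_end - ext_start + 1
    lab = np.zeros(n, dtype=np.int8)  # indices into REGIONS
    idx = {r: i for i, r in enumerate(REGIONS)}

    def paint(s: int, e: int, label: str) -> None:
        s = max(s, ext_start)
        e = min(e, ext_end)
        if s <= e:
            lab[s - ext_start: e - ext_start + 1] = idx[label]

    plus = gene.strand == "+"
    paint(ext_start, gene.start - 1, "upstream" if plus else "downstream")
    paint(gene.end + 1, ext_end, "downstream" if plus else "upstream")
    paint(gene.start, gene.end, "intron")
    if gene.cds:
        cds_lo = min(s for s, _, _ in gene.cds)
        cds_hi = max(e for _, e, _ in gene.cds)
    else:
        cds_lo, cds_hi = gene.end + 1, gene.start - 1
    for s, e in gene.exons:
        # exon portions outside the CDS span are UTR, 5'/3' by strand
        if s < cds_lo:
            paint(s, min(e, cds_lo - 1), "utr5" if plus else "utr3")
        if e > cds_hi:
            paint(max(s, cds_hi + 1), e, "utr3" if plus else "utr5")
    for s, e, _ in gene.cds:
        paint(s, e, "cds")

    blocks: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or lab[i] != lab[start]:
            blocks.append((ext_start + start, ext_start + i - 1,
                           REGIONS[lab[start]]))
            start = i
    return tuple(blocks)


def build_extended_index(genes: Iterable[GeneModel], flank: int = DEFAULT_FLANK,
                         arm_lengths: Mapping[str, int] | None = None
                         ) -> ExtendedGeneIndex:
    """Widen each gene by ``flank`` bp per side and build the region partition.

    Overlapping genes are kept independent (no merging).  A CDS total length
    not divisible by 3 is rejected, naming the gene.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    arm_lengths = dict(arm_lengths or {})
    extended: dict[str, ExtendedGene] = {}
    for g in genes:
        if g.cds and g.cds_length() % 3 != 0:
            raise ValueError(
                f"gene {g.gene_id}: CDS length {g.cds_length()} "
                f"not divisible by 3"
            )
        ext_start = max(1, g.start - flank)
        ext_end = g.end + flank
        if g.arm in arm_lengths:
            ext_end = min(ext_end, arm_lengths[g.arm])
        else:
            arm_lengths.setdefault(g.arm, ext_end)
            arm_lengths[g.arm] = max(arm_lengths[g.arm], ext_end)
        blocks = _partition_gene(g, ext_start, ext_end)
        extended[g.gene_id] = ExtendedGene(g, ext_start, ext_end, blocks)
    return ExtendedGeneIndex(extended, flank, arm_lengths)


def assign_regions(calls: Sequence, index: ExtendedGeneIndex
                   ) -> tuple[list[RegionAssignment], list]:
    """Map each call to every extended gene containing it.

    Returns ``(assignments, intergenic)`` where intergenic lists the calls
    that hit no extended gene; ``len({a.(arm,pos)}) + len(intergenic)``
    equals the number of distinct call loci (conservation).
    """
    assignments: list[RegionAssignment] = []
    intergenic = []
    for call in calls:
        hits = index.overlapping(call.arm, call.pos)
        if not hits:
            intergenic.append(call)
            continue
        multi = len(hits) > 1
        for eg in hits:
            region = eg.region_at(call.pos)
            assert region is not None
            assignments.append(RegionAssignment(
                call.arm, call.pos, eg.gene.gene_id, region, multi))
    return assignments, intergenic


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of ``pos`` within the coding sequence, or None."""
    segs = sorted(gene.cds)
    if gene.strand == "+":
        off = 0
        for s, e, _ in segs:
            if s <= pos <= e:
                return off + (pos - s)
            off += e - s + 1
    else:
        off = 0
        for s, e, _ in reversed(segs):
            if s <= pos <= e:
                return off + (e - pos)
            off += e - s + 1
    return None


def coding_sequence(gene: GeneModel, reference: Mapping[str, str]) -> str:
    """Reconstruct the coding sequence (5'→3' on the coding strand)."""
    seq = reference[gene.arm]
    parts = [seq[s - 1: e] for s, e, _ in sorted(gene.cds)]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def classify_coding(call, gene: GeneModel, reference: Mapping[str, str]
                    ) -> CodingEffect:
    """Classify a SNP inside a gene by codon substitution.

    The alternate allele is taken from the call's ``h_allele``.  Raises on a
    reference mismatch at the call position; a call outside the CDS yields
    effect ``non-coding``.
    """
    arm_seq = reference[call.arm]
    if not (1 <= call.pos <= len(arm_seq)):
        raise ValueError(f"position {call.arm}:{call.pos} outside reference")
    if arm_seq[call.pos - 1] != call.ref:
        raise ValueError(
            f"reference inconsistency at {call.arm}:{call.pos}: "
            f"table says {call.ref}, reference has {arm_seq[call.pos - 1]}"
        )
    off = _cds_offset(gene, call.pos)
    if off is None:
        return CodingEffect(gene.gene_id, -1, "", "", "non-coding")
    cds = coding_sequence(gene, reference)
    alt_base = call.h_allele
    if gene.strand == "-":
        alt_base = str(Seq(alt_base).complement())
    ci = off // 3
    ref_codon = cds[ci * 3: ci * 3 + 3]
    alt_codon = (ref_codon[: off % 3] + alt_base + ref_codon[off % 3 + 1:])
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    elif ref_aa == "*":
        effect = "lost-stop"
    else:
        effect = "nonsynonymous"
    return CodingEffect(gene.gene_id, ci, ref_codon, alt_codon, effect)


def normalize_arm_counts(counts: Mapping[str, int],
                         arm_lengths: Mapping[str, int],
                         ref_arm: str = "X") -> pd.DataFrame:
    """Per-arm polymorphism density, expressed relative to a reference arm.

    Output columns: count, per_kb, rel_to_ref where ``rel_to_ref`` is each
    arm's per-kb density divided by the reference arm's (the X by default),
    i.e. counts normalized to the reference chromosome's size.
    """
    for arm, length in arm_lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length arm {arm!r}")
    if ref_arm not in arm_lengths:
        ref_arm = sorted(arm_lengths)[0]
    rows = []
    ref_density = counts.get(ref_arm, 0) / (arm_lengths[ref_arm] / 1000)
    for arm in sorted(arm_lengths):
        per_kb = counts.get(arm, 0) / (arm_lengths[arm] / 1000)
        rel = per_kb / ref_density if ref_density > 0 else float("nan")
        rows.append({"arm": arm, "count": counts.get(arm, 0),
                     "per_kb": per_kb, "rel_to_ref": rel})
    return pd.DataFrame(rows)


def normalize_region_counts(counts: Mapping[str, int],
                            region_totals: Mapping[str, int],
                            ref_region: str = "intron") -> pd.DataFrame:
    """Per-region counts divided by the total loci of that region class,
    rescaled so the reference class (introns by default) is the unit."""
    rows = []
    if region_totals.get(ref_region, 0) <= 0:
        raise ValueError(f"reference region {ref_region!r} has no loci")
    ref_density = counts.get(ref_region, 0) / region_totals[ref_region]
    for region in REGIONS:
        total = region_totals.get(region, 0)
        if total <= 0:
            continue
        per_locus = counts.get(region, 0) / total
        rel = per_locus / ref_density if ref_density > 0 else float("nan")
        rows.append({"region": region, "count": counts.get(region, 0),
                     "total_loci": total, "per_locus": per_locus,
                     "rel_to_ref": rel})
    return pd.DataFrame(rows)


def mirror_gene(gene: GeneModel) -> GeneModel:
    """Flip a gene to the opposite strand (metamorphic-test helper)."""
    return replace(gene, strand="-" if gene.strand == "+" else "+")
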