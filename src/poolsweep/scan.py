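"""Fixed-difference variant discovery between selected and control pools.

A locus is *evaluable* when depth, consensus base quality and best-read
mapping quality clear their thresholds in all three pools (control C1 and
both selected replicates H1, H2).  At evaluable loci a SNP is called when
each selected pool carries, at >= 90% of its reads, a base that differs from
both the reference and the control consensus, and that base is seen in at
most 10% of control reads.  Indels follow their own four criteria (strand
support typing, >= 10 reads in both selected pools, >= 90% support, absence
from the control).  The false-discovery rate is estimated reciprocally: the
same fixed-vs-rare criterion applied between the two selected replicates,
where a true selection signal must be concordant and hence cannot trigger.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .pool_io import BASES, POOLS, PoolSiteTable

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class QualityThresholds:
    """Evaluable-locus thresholds, applied per pool."""

    min_depth: int = 10
    min_baseq: int = 20
    min_bestq: int = 40

    def __post_init__(self):
        if min(self.min_depth, self.min_baseq, self.min_bestq) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class CallerConfig:
    fix_threshold: float = 0.90
    rare_threshold: float = 0.10
    require_h_identity: bool = False
    control_absence_max_reads: int = 0
    #: denominator for pool base frequencies: the sum of A/C/G/T base calls
    #: ("basecalls", default — gapped/N reads do not dilute) or raw "depth"
    freq_denominator: str = "basecalls"

    def __post_init__(self):
        if not self.rare_threshold < self.fix_threshold:
            raise ValueError("rare_threshold must be < fix_threshold")
        if self.freq_denominator not in ("basecalls", "depth"):
            raise ValueError("freq_denominator must be 'basecalls' or 'depth'")


@dataclass(frozen=True)
class SnpCall:
    arm: str
    pos: int
    ref: str
    h_allele: str      # H1's fixed base
    h2_allele: str     # H2's fixed base (== h_allele unless discordant)
    c_consensus: str
    freq_H1: float     # frequency of h_allele in H1
    freq_H2: float     # frequency of h2_allele in H2
    freq_C1: float     # frequency of h_allele in C1
    h_identity: bool


@dataclass(frozen=True)
class IndelCall:
    arm: str
    pos: int
    ref: str
    kind: str          # "ins" or "del"
    seq: str           # deleted base for "del"; "N" when unknown (ins)
    maq_type: str      # "*" (both strands) or "+" (>=2 reads, one strand)
    support_H1: float
    support_H2: float
    control_support_reads: int
    homopolymer_flag: bool = False


@dataclass(frozen=True)
class FdrEstimate:
    reciprocal_false_loci: int
    called_snps: int
    fdr: float
    denominator: str = "called"  # "called" or "evaluable"
    evaluable_loci: int = 0


def evaluable_mask(table: PoolSiteTable,
                   thresholds: QualityThresholds = QualityThresholds()
                   ) -> tuple[np.ndarray, dict[str, float]]:
    """Boolean mask of evaluable sites plus the evaluable fraction per arm.

    A site is evaluable iff depth, baseq and bestq meet the thresholds in all
    three pools.
    """
    df = table.df
    mask = np.ones(len(df), dtype=bool)
    for pool in POOLS:
        mask &= df[f"{pool}_depth"].to_numpy() >= thresholds.min_depth
        mask &= df[f"{pool}_baseq"].to_numpy() >= thresholds.min_baseq
        mask &= df[f"{pool}_bestq"].to_numpy() >= thresholds.min_bestq
    fractions = {}
    arms = df["arm"].to_numpy()
    for arm in np.unique(arms):
        sel = arms == arm
        fractions[str(arm)] = float(mask[sel].mean()) if sel.any() else 0.0
    return mask, fractions


def _pool_freqs(table: PoolSiteTable, pool: str, config: CallerConfig
                ) -> np.ndarray:
    """(n, 4) base frequencies; rows with a zero denominator are all-zero."""
    counts = table.base_counts(pool).astype(float)
    if config.freq_denominator == "basecalls":
        denom = counts.sum(axis=1)
    else:
        denom = table.depth(pool).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom[:, None] > 0, counts / denom[:, None], 0.0)
    return freqs


def _c1_consensus(table: PoolSiteTable, ref_idx: np.ndarray) -> np.ndarray:
    """Majority base index in C1 per site; ties broken toward the reference,
    then by A<C<G<T order (conservative at ambiguous control sites)."""
    counts = table.base_counts("C1")
    maxc = counts.max(axis=1)
    ref_is_max = counts[np.arange(len(counts)), ref_idx] == maxc
    argmax = counts.argmax(axis=1)  # first max in A,C,G,T order
    return np.where(ref_is_max, ref_idx, argmax)


def _candidate_alleles(freqs: np.ndarray, ref_idx: np.ndarray,
                       cons_idx: np.ndarray, c1_freqs: np.ndarray,
                       config: CallerConfig) -> np.ndarray:
    """Per site, the index of the selected-pool candidate base, or -1.

    A candidate must reach ``fix_threshold`` in its own pool, differ from the
    reference and the control consensus, and sit at or below
    ``rare_threshold`` in the control.  If several bases qualify (possible
    only when ``fix_threshold`` <= 0.5) the most frequent wins, ties broken
    by A<C<G<T order.
    """
    n = freqs.shape[0]
    ok = freqs >= config.fix_threshold
    cols = np.arange(4)
    ok &= cols[None, :] != ref_idx[:, None]
    ok &= cols[None, :] != cons_idx[:, None]
    ok &= c1_freqs <= config.rare_threshold
    masked = np.where(ok, freqs, -1.0)
    best = masked.argmax(axis=1)
    has = masked[np.arange(n), best] >= 0
    return np.where(has, best, -1)


def call_snps(table: PoolSiteTable, mask: np.ndarray,
              config: CallerConfig = CallerConfig()) -> list[SnpCall]:
    """Call fixed-difference SNPs at evaluable sites.

    Sites outside ``mask`` are never called.  H1/H2 allele identity is
    recorded on every call and only *required* when
    ``config.require_h_identity`` is set.
    """
    df = table.df
    n = len(df)
    if n == 0:
        return []
    ref_idx = df["ref"].map(_BASE_IDX).to_numpy()
    fC1 = _pool_freqs(table, "C1", config)
    fH1 = _pool_freqs(table, "H1", config)
    fH2 = _pool_freqs(table, "H2", config)
    cons = _c1_consensus(table, ref_idx)
    cand1 = _candidate_alleles(fH1, ref_idx, cons, fC1, config)
    cand2 = _candidate_alleles(fH2, ref_idx, cons, fC1, config)
    callable_ = mask & (cand1 >= 0) & (cand2 >= 0)
    if config.require_h_identity:
        callable_ &= cand1 == cand2
    calls: list[SnpCall] = []
    arms = df["arm"].to_numpy()
    poss = df["pos"].to_numpy()
    refs = df["ref"].to_numpy()
    for i in np.nonzero(callable_)[0]:
        a1, a2 = int(cand1[i]), int(cand2[i])
        calls.append(SnpCall(
            arm=str(arms[i]), pos=int(poss[i]), ref=str(refs[i]),
            h_allele=BASES[a1], h2_allele=BASES[a2],
            c_consensus=BASES[int(cons[i])],
            freq_H1=float(fH1[i, a1]), freq_H2=float(fH2[i, a2]),
            freq_C1=float(fC1[i, a1]), h_identity=a1 == a2,
        ))
    return calls


def call_indels(table: PoolSiteTable, mask: np.ndarray | None = None,
                config: CallerConfig = CallerConfig(),
                reference: Mapping[str, str] | None = None) -> list[IndelCall]:
    """Call fixed indels using the four-part criterion.

    1. strand typing: "*" needs >= 1 supporting read on each strand (summed
       over H1+H2), "+" needs >= 2 supporting reads on one strand;
    2. >= ``min`` 10 reads depth in both H1 and H2 (their own coverage rule —
       pass ``mask`` to additionally restrict to the SNP evaluable mask);
    3. support fraction >= ``fix_threshold`` of reads in both H1 and H2;
    4. at most ``control_absence_max_reads`` supporting reads in C1.

    Deletion calls record the deleted reference base when ``reference`` is
    given (our tables carry single-base events); insertion sequences are not
    represented in count tables and are recorded as "N".
    """
    df = table.df
    calls: list[IndelCall] = []
    depth_h1 = table.depth("H1")
    depth_h2 = table.depth("H2")
    for kind in ("del", "ins"):
        s1 = df[f"H1_{kind}"].to_numpy()
        s2 = df[f"H2_{kind}"].to_numpy()
        c = df[f"C1_{kind}"].to_numpy()
        fwd = df[f"H1_{kind}_fwd"].to_numpy() + df[f"H2_{kind}_fwd"].to_numpy()
        rev = df[f"H1_{kind}_rev"].to_numpy() + df[f"H2_{kind}_rev"].to_numpy()
        both_strands = (fwd >= 1) & (rev >= 1)
        same_strand = np.maximum(fwd, rev) >= 2
        typed = both_strands | same_strand
        covered = (depth_h1 >= 10) & (depth_h2 >= 10)
        with np.errstate(invalid="ignore", divide="ignore"):
            sup1 = np.where(depth_h1 > 0, s1 / depth_h1, 0.0)
            sup2 = np.where(depth_h2 > 0, s2 / depth_h2, 0.0)
        fixed = (sup1 >= config.fix_threshold) & (sup2 >= config.fix_threshold)
        absent_c = c <= config.control_absence_max_reads
        ok = typed & covered & fixed & absent_c
        if mask is not None:
            ok &= mask
        for i in np.nonzero(ok)[0]:
            arm = str(df["arm"].iloc[i])
            pos = int(df["pos"].iloc[i])
            ref = str(df["ref"].iloc[i])
            if kind == "del":
                seq = reference[arm][pos - 1] if reference else ref
            else:
                seq = "N"
            calls.append(IndelCall(
                arm=arm, pos=pos, ref=ref, kind=kind, seq=seq,
                maq_type="*" if both_strands[i] else "+",
                support_H1=float(sup1[i]), support_H2=float(sup2[i]),
                control_support_reads=int(c[i]),
            ))
    calls.sort(key=lambda c: (c.arm, c.pos))
    return calls


def reciprocal_false_loci(table: PoolSiteTable, mask: np.ndarray,
                          config: CallerConfig = CallerConfig()) -> int:
    """Count evaluable loci fixed in one selected replicate and rare in the
    other (either direction; a locus counts once)."""
    df = table.df
    if len(df) == 0:
        return 0
    ref_idx = df["ref"].map(_BASE_IDX).to_numpy()
    fH1 = _pool_freqs(table, "H1", config)
    fH2 = _pool_freqs(table, "H2", config)
    cols = np.arange(4)
    non_ref = cols[None, :] != ref_idx[:, None]
    dir1 = ((fH1 >= config.fix_threshold) & (fH2 <= config.rare_threshold)
            & non_ref).any(axis=1)
    dir2 = ((fH2 >= config.fix_threshold) & (fH1 <= config.rare_threshold)
            & non_ref).any(axis=1)
    return int((mask & (dir1 | dir2)).sum())


def estimate_fdr_reciprocal(table: PoolSiteTable, mask: np.ndarray,
                            config: CallerConfig, called_snps: int,
                            denominator: str = "called") -> FdrEstimate:
    """Reciprocal-replicate FDR estimate.

    ``denominator="called"`` divides the reciprocal locus count by the number
    of called SNPs (the convention recovering the study's printed rate);
    ``"evaluable"`` divides by the number of evaluable loci, giving a
    per-locus false-call rate.
    """
    count = reciprocal_false_loci(table, mask, config)
    n_eval = int(mask.sum())
    if denominator == "called":
        if called_snps == 0:
            if count > 0:
                raise ZeroDivisionError(
                    "undefined FDR: reciprocal loci found but no SNPs called")
            fdr = 0.0
        else:
            fdr = count / called_snps
    elif denominator == "evaluable":
        fdr = count / n_eval if n_eval else 0.0
    else:
        raise ValueError("denominator must be 'called' or 'evaluable'")
    return FdrEstimate(count, called_snps, fdr, denominator, n_eval)


# ---------------------------------------------------------------------------
# Homopolymer flagging

def _max_run_near(seq: str, pos0: int, base: str | None) -> int:
    """Length of the longest run touching index ``pos0`` (0-based) or its
    immediate neighbours; restricted to ``base`` when given."""
    best = 0
    for anchor in (pos0 - 1, pos0, pos0 + 1):
        if not (0 <= anchor < len(seq)):
            continue
        b = seq[anchor]
        if base is not None and b != base:
            continue
        lo = anchor
        while lo > 0 and seq[lo - 1] == b:
            lo -= 1
        hi = anchor
        while hi < len(seq) - 1 and seq[hi + 1] == b:
            hi += 1
        best = max(best, hi - lo + 1)
    return best


def flag_homopolymer(indel_calls: Sequence[IndelCall],
                     reference: Mapping[str, str],
                     min_run: int = 5) -> list[IndelCall]:
    """Flag indels abutting a reference homopolymer run of length >= min_run.

    Deletions check the run of the deleted base around the call position; an
    insertion of unknown sequence is flagged whenever any single-base run of
    at least ``min_run`` touches the insertion point.  Calls are annotated,
    never dropped.
    """
    flagged = []
    for call in indel_calls:
        seq = reference[call.arm]
        if not (1 <= call.pos <= len(seq)):
            raise ValueError(f"position {call.arm}:{call.pos} outside reference")
        if call.kind == "del" and call.seq != "N":
            if len(set(call.seq)) != 1:
                flagged.append(replace(call, homopolymer_flag=False))
                continue
            run = _max_run_near(seq, call.pos - 1, call.seq[0])
        else:
            run = _max_run_near(seq, call.pos - 1, None)
        flagged.append(replace(call, homopolymer_flag=run >= min_run))
    return flagged


def homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int, str]]:
    """All maximal single-base runs of length >= min_run, 0-based half-open.

    Exposed for reporting; the test suite checks :func:`flag_homopolymer`
    against an independent regex scanner instead of this helper.
    """
    out = []
    for m in re.finditer(r"(.)\1{" + str(min_run - 1) + r",}", seq):
        out.append((m.start(), m.end(), m.group(1)))
    return out
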