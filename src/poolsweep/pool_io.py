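"""Readers and writers for the pool-seq count table and companion formats.

The central format is a per-locus TSV carrying, for each of the three pools
(one control ``C1`` and two selected replicates ``H1``/``H2``), the read
depth, A/C/G/T base counts, indel read support with a per-strand breakdown,
and the two alignment-quality summaries (consensus base quality and best
supporting-read mapping quality) used by the evaluable-locus mask.

Files are 1-based inclusive (GFF3/VCF convention); all in-memory interval
arithmetic elsewhere in the package is 0-based half-open, with conversion
confined to this module and to :mod:`poolsweep.annotate`.

Readers validate and reject; they never silently repair a malformed row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

POOLS = ("C1", "H1", "H2")
BASES = ("A", "C", "G", "T")
POOL_FIELDS = (
    "depth", "A", "C", "G", "T",
    "del", "ins", "del_fwd", "del_rev", "ins_fwd", "ins_rev",
    "baseq", "bestq",
)

#: Column order of the pool count TSV dialect.
TABLE_COLUMNS = ["arm", "pos", "ref"] + [
    f"{pool}_{field}" for pool in POOLS for field in POOL_FIELDS
]


class PoolTableError(ValueError):
    """A pool count table violated a structural invariant."""


class PoolSiteTable:
    """Per-locus pooled counts for the three pools, keyed by (arm, pos).

    Wraps a :class:`pandas.DataFrame` with the columns of
    :data:`TABLE_COLUMNS`.  Rows are kept sorted by (arm, pos); positions are
    1-based.  The sum of A/C/G/T counts may fall short of depth (gapped or
    masked reads) but never exceed it.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise PoolTableError(f"missing columns: {missing}")
        df = df.loc[:, TABLE_COLUMNS].reset_index(drop=True)
        df = df.sort_values(["arm", "pos"], kind="stable").reset_index(drop=True)
        self.df = df
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, PoolSiteTable) and self.df.equals(other.df)

    def validate(self) -> None:
        df = self.df
        bad: list[str] = []
        if not df["ref"].isin(BASES).all():
            rows = df.index[~df["ref"].isin(BASES)].tolist()
            bad.append(f"ref not in {BASES} at rows {rows[:10]}")
        dup = df.duplicated(subset=["arm", "pos"])
        if dup.any():
            keys = df.loc[dup, ["arm", "pos"]].values.tolist()
            bad.append(f"duplicate (arm, pos): {keys[:10]}")
        for pool in POOLS:
            depth = df[f"{pool}_depth"].to_numpy()
            base_sum = sum(df[f"{pool}_{b}"].to_numpy() for b in BASES)
            over = np.nonzero(base_sum > depth)[0]
            if over.size:
                bad.append(
                    f"{pool} base counts exceed depth at rows {over[:10].tolist()}"
                )
            for kind in ("del", "ins"):
                tot = df[f"{pool}_{kind}"].to_numpy()
                split = (
                    df[f"{pool}_{kind}_fwd"].to_numpy()
                    + df[f"{pool}_{kind}_rev"].to_numpy()
                )
                off = np.nonzero(tot != split)[0]
                if off.size:
                    bad.append(
                        f"{pool} {kind} strand split != total at rows "
                        f"{off[:10].tolist()}"
                    )
            numeric = [f"{pool}_{f}" for f in POOL_FIELDS]
            neg = (df[numeric] < 0).any(axis=1)
            if neg.any():
                bad.append(f"negative {pool} fields at rows "
                           f"{df.index[neg][:10].tolist()}")
        if bad:
            raise PoolTableError("; ".join(bad))

    # convenience accessors -------------------------------------------------
    def base_counts(self, pool: str) -> np.ndarray:
        """(n_sites, 4) array of A/C/G/T counts for one pool."""
        return self.df[[f"{pool}_{b}" for b in BASES]].to_numpy(dtype=np.int64)

    def depth(self, pool: str) -> np.ndarray:
        return self.df[f"{pool}_depth"].to_numpy(dtype=np.int64)


def read_pool_table(path: str | Path) -> PoolSiteTable:
    """Read the pool count TSV, reporting malformed rows by file line number.

    Line 1 is the header; data lines are numbered from 2.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != TABLE_COLUMNS:
        raise PoolTableError(
            f"{path}: header does not match pool-table dialect "
            f"(got {len(header)} columns, expected {len(TABLE_COLUMNS)})"
        )
    df = pd.read_csv(path, sep="\t", dtype={"arm": str, "ref": str})
    int_cols = [c for c in TABLE_COLUMNS if c not in ("arm", "ref")]
    for c in int_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise PoolTableError(f"{path}: non-integer '{c}' at lines {lines[:10]}")
        df[c] = vals.astype(np.int64)
    try:
        return PoolSiteTable(df)
    except PoolTableError as exc:
        # validation reports 0-based row indices; translate to file lines
        raise PoolTableError(
            f"{path}: {exc} (row r is file line r+2)"
        ) from exc


def write_pool_table(table: PoolSiteTable, path: str | Path) -> None:
    """Write the table, stable-sorted by (arm, pos), in the TSV dialect."""
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PoPoolation2-style sync import

_SYNC_ORDER = ("A", "T", "C", "G", "N", "del")  # fixed field order of sync


def import_sync(path: str | Path, default_baseq: int,
                default_bestq: int) -> PoolSiteTable:
    """Import a 3-pool sync file (``chrom pos ref A:T:C:G:N:del`` per pool).

    Pool columns map to C1, H1, H2 in file order.  N counts are kept in the
    depth but excluded from base counts.  Sync carries no quality fields;
    they are filled with the given defaults and the table is flagged via the
    ``quality_defaults_filled`` attribute.  Sync also carries no strand
    breakdown for deletions; all deletion support is recorded on the forward
    strand (conservative: indel typing then follows the same-strand rule).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + len(POOLS):
                raise PoolTableError(
                    f"{path}:{lineno}: expected {3 + len(POOLS)} columns, "
                    f"got {len(fields)}"
                )
            arm, pos, ref = fields[0], int(fields[1]), fields[2].upper()
            row: dict = {"arm": arm, "pos": pos, "ref": ref}
            for pool, cell in zip(POOLS, fields[3:]):
                parts = cell.split(":")
                if len(parts) != 6:
                    raise PoolTableError(
                        f"{path}:{lineno}: malformed sync cell '{cell}'"
                    )
                counts = dict(zip(_SYNC_ORDER, (int(x) for x in parts)))
                row[f"{pool}_depth"] = sum(counts.values())
                for b in BASES:
                    row[f"{pool}_{b}"] = counts[b]
                row[f"{pool}_del"] = counts["del"]
                row[f"{pool}_del_fwd"] = counts["del"]
                row[f"{pool}_del_rev"] = 0
                for f in ("ins", "ins_fwd", "ins_rev"):
                    row[f"{pool}_{f}"] = 0
                row[f"{pool}_baseq"] = default_baseq
                row[f"{pool}_bestq"] = default_bestq
            rows.append(row)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=(str if c in ("arm", "ref") else np.int64))
         for c in TABLE_COLUMNS}
    )
    table = PoolSiteTable(df)
    table.quality_defaults_filled = True  # type: ignore[attr-defined]
    return table


def export_sync(table: PoolSiteTable, path: str | Path) -> None:
    """Export counts in sync form (drops quality and strand information)."""
    with open(path, "w") as fh:
        for _, r in table.df.iterrows():
            cells = []
            for pool in POOLS:
                n = (r[f"{pool}_depth"]
                     - sum(r[f"{pool}_{b}"] for b in BASES)
                     - r[f"{pool}_del"])
                cells.append(":".join(str(int(x)) for x in (
                    r[f"{pool}_A"], r[f"{pool}_T"], r[f"{pool}_C"],
                    r[f"{pool}_G"], max(int(n), 0), r[f"{pool}_del"])))
            fh.write(f"{r['arm']}\t{r['pos']}\t{r['ref']}\t" +
                     "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Variant-call output

SNP_TSV_COLUMNS = ("arm", "pos", "ref", "h_allele", "h2_allele", "c_consensus",
                   "freq_H1", "freq_H2", "freq_C1", "h_identity")
INDEL_TSV_COLUMNS = ("arm", "pos", "ref", "kind", "seq", "maq_type",
                     "support_H1", "support_H2", "control_support_reads",
                     "homopolymer_flag")

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=FH1,Number=1,Type=Float,Description="Frequency of the selected allele in pool H1">
##INFO=<ID=FH2,Number=1,Type=Float,Description="Frequency of the selected allele in pool H2">
##INFO=<ID=FC1,Number=1,Type=Float,Description="Frequency of the selected allele in control pool C1">
##INFO=<ID=HID,Number=0,Type=Flag,Description="H1 and H2 carry the identical allele">
##INFO=<ID=CSUP,Number=1,Type=Integer,Description="Supporting reads in the control pool (indels)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _sorted_calls(calls: Sequence) -> list:
    ordered = sorted(calls, key=lambda c: (c.arm, c.pos))
    if list(ordered) != list(calls):
        logger.warning("calls were unsorted; sorted by (arm, pos) before write")
    return ordered


def write_calls(calls: Sequence, path: str | Path, fmt: str = "tsv",
                reference: Mapping[str, str] | None = None) -> None:
    """Write SNP or indel calls as TSV or (SNPs) minimal VCF 4.2.

    ``calls`` must be homogeneous (all SNP calls or all indel calls).  Indel
    VCF output needs the reference for the anchor-base convention.
    """
    calls = _sorted_calls(calls)
    if fmt == "tsv":
        _write_calls_tsv(calls, path)
    elif fmt == "vcf":
        _write_calls_vcf(calls, path, reference)
    else:
        raise ValueError(f"unknown call format: {fmt!r}")


def _is_indel(call) -> bool:
    return hasattr(call, "maq_type")


def _write_calls_tsv(calls: Sequence, path: str | Path) -> None:
    indel = bool(calls) and _is_indel(calls[0])
    cols = INDEL_TSV_COLUMNS if indel else SNP_TSV_COLUMNS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            vals = []
            for name in cols:
                v = getattr(c, name)
                if isinstance(v, float):
                    v = f"{v:.6f}"
                elif isinstance(v, bool):
                    v = int(v)
                vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def _write_calls_vcf(calls: Sequence, path: str | Path,
                     reference: Mapping[str, str] | None) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in calls:
            if _is_indel(c):
                if reference is None:
                    raise ValueError("indel VCF output requires the reference")
                seq = reference[c.arm]
                anchor_pos = c.pos - 1  # base before the event, 1-based
                anchor = seq[anchor_pos - 1]
                if c.kind == "del":
                    ref_field = anchor + seq[c.pos - 1]
                    alt_field = anchor
                else:
                    ref_field = anchor
                    alt_field = anchor + c.seq
                info = (f"FH1={c.support_H1:.6f};FH2={c.support_H2:.6f};"
                        f"CSUP={c.control_support_reads}")
                fh.write(f"{c.arm}\t{anchor_pos}\t.\t{ref_field}\t{alt_field}"
                         f"\t.\tPASS\t{info}\n")
            else:
                alt = c.h_allele
                if not c.h_identity and c.h2_allele != c.h_allele:
                    alt = f"{c.h_allele},{c.h2_allele}"
                info = (f"FH1={c.freq_H1:.6f};FH2={c.freq_H2:.6f};"
                        f"FC1={c.freq_C1:.6f}")
                if c.h_identity:
                    info += ";HID"
                fh.write(f"{c.arm}\t{c.pos}\t.\t{c.ref}\t{alt}\t.\tPASS"
                         f"\t{info}\n")


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    """Parse back a calls TSV written by :func:`write_calls`."""
    return pd.read_csv(path, sep="\t", dtype={"arm": str})


# ---------------------------------------------------------------------------
# FASTA / GFF3 / pathway sets

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=arm, description="")
               for arm, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Iterable, arm_lengths: Mapping[str, int],
               path: str | Path) -> None:
    """Write gene models (gene/mRNA/exon/CDS) as GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for arm in sorted(arm_lengths):
            fh.write(f"##sequence-region {arm} 1 {arm_lengths[arm]}\n")
        for g in sorted(genes, key=lambda g: (g.arm, g.start)):
            base = (g.arm, "poolsweep")
            fh.write("\t".join(map(str, (
                *base, "gene", g.start, g.end, ".", g.strand, ".",
                f"ID={g.gene_id}"))) + "\n")
            mrna = f"{g.gene_id}.t1"
            fh.write("\t".join(map(str, (
                *base, "mRNA", g.start, g.end, ".", g.strand, ".",
                f"ID={mrna};Parent={g.gene_id}"))) + "\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write("\t".join(map(str, (
                    *base, "exon", s, e, ".", g.strand, ".",
                    f"ID={mrna}.exon{i};Parent={mrna}"))) + "\n")
            for i, (s, e, phase) in enumerate(g.cds, start=1):
                fh.write("\t".join(map(str, (
                    *base, "CDS", s, e, ".", g.strand, phase,
                    f"ID={mrna}.cds;Parent={mrna}"))) + "\n")


def read_gff3(path: str | Path):
    """Read gene models from GFF3 via gffutils.

    Returns ``(genes, arm_lengths)`` where genes is a list of
    :class:`poolsweep.annotate.GeneModel` and arm_lengths comes from the
    ``##sequence-region`` pragmas (empty dict if absent).
    """
    import gffutils

    from .annotate import GeneModel

    path = Path(path)
    arm_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, arm, start, end = line.split()
                arm_lengths[arm] = int(end)
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        cds = []
        for f in db.children(g, featuretype="exon", order_by="start"):
            exons.append((f.start, f.end))
        for f in db.children(g, featuretype="CDS", order_by="start"):
            phase = int(f.frame) if f.frame not in (None, ".") else 0
            cds.append((f.start, f.end, phase))
        genes.append(GeneModel(gene_id=g.id, arm=g.seqid, strand=g.strand,
                               start=g.start, end=g.end,
                               exons=tuple(exons), cds=tuple(cds)))
    return genes, arm_lengths


def read_pathway_sets(path: str | Path) -> dict[str, set[str]]:
    """Read pathway sets: one per line, ``name<TAB>comma-separated gene IDs``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                name, members = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 2 columns") from exc
            if not name:
                raise ValueError(f"{path}:{lineno}: empty set name")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {name!r}")
            ids = [m for m in members.split(",") if m]
            if len(ids) != len(set(ids)):
                raise ValueError(f"{path}:{lineno}: duplicate members in {name!r}")
            sets[name] = set(ids)
    return sets


def write_pathway_sets(sets: Mapping[str, Iterable[str]],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write(f"{name}\t{','.join(sorted(sets[name]))}\n")
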