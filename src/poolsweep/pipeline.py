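"""Reproducible simulate -> scan -> annotate -> enrich -> report pipeline.

A single global seed deterministically derives per-stage substreams, so a
re-run with an identical config reproduces byte-identical non-log outputs.
Every stage writes plain-text artifacts into the run directory; the report
is regenerated purely from those artifacts and carries the config hash and
seed for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, enrich, pool_io, scan, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "annotate", "enrich", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration for one end-to-end run.

    Section defaults echo the module defaults; the demo scale (two 50 kb
    arms, 50 genes, 10 planted sweeps) runs in seconds.
    """

    sim: simulate.SimConfig = field(default_factory=lambda: simulate.SimConfig(
        genome_length=50_000, n_arms=2))
    seq: simulate.SeqConfig = field(default_factory=simulate.SeqConfig)
    thresholds: scan.QualityThresholds = field(
        default_factory=scan.QualityThresholds)
    caller: scan.CallerConfig = field(default_factory=scan.CallerConfig)
    polymorphic_site_density: float = 5.0  # sites per kb
    indel_fraction: float = 0.1
    n_targets: int = 10
    n_indel_targets: int = 2
    selection_s: float = 0.2
    n_genes: int = 50
    n_pathways: int = 5
    flank: int = annotate.DEFAULT_FLANK
    min_homopolymer_run: int = 5
    fdr_denominator: str = "called"
    mask_aware_enrichment: bool = False
    mu_nonredundant: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["selection_targets"] = [
            list(t) for t in d["sim"]["selection_targets"]]
        if d["sim"]["arm_names"] is not None:
            d["sim"]["arm_names"] = list(d["sim"]["arm_names"])
        if d["sim"]["pop_size_schedule"] is not None:
            d["sim"]["pop_size_schedule"] = list(d["sim"]["pop_size_schedule"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        sim["selection_targets"] = tuple(
            tuple(t) for t in sim.get("selection_targets", ()))
        if sim.get("arm_names") is not None:
            sim["arm_names"] = tuple(sim["arm_names"])
        if sim.get("pop_size_schedule") is not None:
            sim["pop_size_schedule"] = tuple(sim["pop_size_schedule"])
        kwargs = {
            "sim": simulate.SimConfig(**sim),
            "seq": simulate.SeqConfig(**d.pop("seq", {})),
            "thresholds": scan.QualityThresholds(**d.pop("thresholds", {})),
            "caller": scan.CallerConfig(**d.pop("caller", {})),
        }
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {name: np.random.default_rng(child)
            for name, child in zip(STAGES, children)}


_FLOAT_FMT = "%.6g"


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage in order; returns the run directory.

    A stage failure writes a FAILED marker naming the stage, keeps partial
    outputs, and raises :class:`PipelineError`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")
    rngs = _stage_rngs(config.seed)
    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            globals()[f"_stage_{stage}"](config, outdir, rngs[stage], state)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", stage,
                    time.perf_counter() - t0)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir


def _stage_simulate(config: PipelineConfig, outdir: Path,
                    rng: np.random.Generator, state: dict) -> None:
    result = simulate.simulate_experiment(
        config.sim, config.seq, rng,
        polymorphic_site_density=config.polymorphic_site_density,
        n_genes=config.n_genes, n_pathways=config.n_pathways,
        n_targets=config.n_targets, s=config.selection_s,
        n_indel_targets=config.n_indel_targets,
        indel_fraction=config.indel_fraction)
    pool_io.write_fasta(result.reference, outdir / "reference.fasta")
    pool_io.write_gff3(result.genes, config.sim.arm_lengths,
                       outdir / "genes.gff3")
    pool_io.write_pathway_sets(result.pathway_sets, outdir / "pathways.tsv")
    pool_io.write_pool_table(result.table, outdir / "pool_table.tsv")
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
    with open(outdir / "targets.tsv", "w") as fh:
        fh.write("arm\tpos\ts\n")
        for arm, pos, s in result.targets:
            fh.write(f"{arm}\t{pos}\t{s:g}\n")
    state["result"] = result


def _stage_scan(config: PipelineConfig, outdir: Path,
                rng: np.random.Generator, state: dict) -> None:
    table = pool_io.read_pool_table(outdir / "pool_table.tsv")
    reference = pool_io.read_fasta(outdir / "reference.fasta")
    mask, fractions = scan.evaluable_mask(table, config.thresholds)
    snps = scan.call_snps(table, mask, config.caller)
    indels = scan.call_indels(table, mask=None, config=config.caller,
                              reference=reference)
    indels = scan.flag_homopolymer(indels, reference,
                                   min_run=config.min_homopolymer_run)
    fdr = scan.estimate_fdr_reciprocal(table, mask, config.caller,
                                       called_snps=len(snps),
                                       denominator=config.fdr_denominator)
    pool_io.write_calls(snps, outdir / "snp_calls.tsv", "tsv")
    pool_io.write_calls(snps, outdir / "snp_calls.vcf", "vcf")
    pool_io.write_calls(indels, outdir / "indel_calls.tsv", "tsv")
    with open(outdir / "fdr.tsv", "w") as fh:
        fh.write("reciprocal_false_loci\tcalled_snps\tevaluable_loci"
                 "\tdenominator\tfdr\n")
        fh.write(f"{fdr.reciprocal_false_loci}\t{fdr.called_snps}"
                 f"\t{fdr.evaluable_loci}\t{fdr.denominator}\t{fdr.fdr:.6g}\n")
    with open(outdir / "evaluable_fraction.tsv", "w") as fh:
        fh.write("arm\tfraction\n")
        for arm in sorted(fractions):
            fh.write(f"{arm}\t{fractions[arm]:.6g}\n")
    evaluable = table.df[["arm", "pos"]].copy()
    evaluable["evaluable"] = mask.astype(int)
    evaluable.to_csv(outdir / "evaluable_sites.tsv", sep="\t", index=False)
    state.update(table=table, mask=mask, snps=snps, indels=indels, fdr=fdr)


def _stage_annotate(config: PipelineConfig, outdir: Path,
                    rng: np.random.Generator, state: dict) -> None:
    genes, arm_lengths = pool_io.read_gff3(outdir / "genes.gff3")
    for arm, length in config.sim.arm_lengths.items():
        arm_lengths.setdefault(arm, length)
    reference = pool_io.read_fasta(outdir / "reference.fasta")
    index = annotate.build_extended_index(genes, flank=config.flank,
                                          arm_lengths=arm_lengths)
    calls = list(state["snps"]) + list(state["indels"])
    assignments, intergenic = annotate.assign_regions(calls, index)
    effects = {}
    for call in state["snps"]:
        for eg in index.overlapping(call.arm, call.pos):
            if eg.region_at(call.pos) == "cds":
                eff = annotate.classify_coding(call, eg.gene, reference)
                effects[(call.arm, call.pos, eg.gene.gene_id)] = eff.effect
    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("arm\tpos\tgene_id\tregion\tmulti_gene\teffect\n")
        for a in sorted(assignments, key=lambda a: (a.arm, a.pos, a.gene_id)):
            eff = effects.get((a.arm, a.pos, a.gene_id), ".")
            fh.write(f"{a.arm}\t{a.pos}\t{a.gene_id}\t{a.region}"
                     f"\t{int(a.multi_gene)}\t{eff}\n")
    state.update(index=index, assignments=assignments, intergenic=intergenic)


def _stage_enrich(config: PipelineConfig, outdir: Path,
                  rng: np.random.Generator, state: dict) -> None:
    index = state["index"]
    assignments = state["assignments"]
    calls = list(state["snps"]) + list(state["indels"])
    if not calls or not index.genes:
        (outdir / "densities.tsv").write_text(
            "gene_id\tcount\text_kb\tdensity\tmultiple\n")
        (outdir / "enrichment.tsv").write_text("set\tN\tK\tn\tk\tp\tq_bh\n")
        state["mu"] = float("nan")
        return
    stats = enrich.compute_density_stats(assignments, index,
                                         nonredundant_mu=config.mu_nonredundant)
    stats.per_gene.to_csv(outdir / "densities.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
    pathway_sets = pool_io.read_pathway_sets(outdir / "pathways.tsv")
    mask_loci = None
    if config.mask_aware_enrichment:
        df = state["table"].df
        mask = state["mask"]
        mask_loci = {(str(a), int(p)) for a, p in
                     zip(df["arm"][mask], df["pos"][mask])}
    table = enrich.enrich_all(calls, index, pathway_sets, mask_loci=mask_loci)
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    state["mu"] = stats.mu


def _stage_report(config: PipelineConfig, outdir: Path,
                  rng: np.random.Generator, state: dict) -> None:
    write_report(outdir)


def write_report(outdir: str | Path) -> Path:
    """(Re)generate report.txt from the run directory's artifacts only.

    Regeneration from an unchanged directory is byte-identical.
    """
    outdir = Path(outdir)
    config = PipelineConfig.from_yaml(outdir / "config_used.yaml")
    lines: list[str] = []
    lines.append("poolsweep run report")
    lines.append(f"config_hash: {config.hash()}  seed: {config.seed}")
    lines.append("")
    lines.append("[thresholds]")
    lines.append(f"min_depth={config.thresholds.min_depth} "
                 f"min_baseq={config.thresholds.min_baseq} "
                 f"min_bestq={config.thresholds.min_bestq}")
    lines.append(f"fix_threshold={config.caller.fix_threshold} "
                 f"rare_threshold={config.caller.rare_threshold} "
                 f"require_h_identity={config.caller.require_h_identity} "
                 f"control_indel_max={config.caller.control_absence_max_reads}")
    lines.append(f"flank={config.flank} "
                 f"min_homopolymer_run={config.min_homopolymer_run} "
                 f"fdr_denominator={config.fdr_denominator}")
    lines.append("")

    def _read(name: str) -> pd.DataFrame | None:
        path = outdir / name
        if not path.exists():
            return None
        return pd.read_csv(path, sep="\t", dtype={"arm": str})

    snps = _read("snp_calls.tsv")
    indels = _read("indel_calls.tsv")
    truth = _read("truth.tsv")
    for label, df in (("snp", snps), ("indel", indels)):
        lines.append(f"[{label} calls]")
        if df is None:
            lines.append("stage not run")
        else:
            lines.append(f"total: {len(df)}")
            if len(df):
                for arm, cnt in df.groupby("arm").size().items():
                    lines.append(f"  {arm}: {cnt}")
        lines.append("")
    frac = _read("evaluable_fraction.tsv")
    lines.append("[evaluable fraction]")
    if frac is None:
        lines.append("stage not run")
    else:
        for _, r in frac.iterrows():
            lines.append(f"  {r['arm']}: {r['fraction']:.4g}")
    lines.append("")
    fdr = _read("fdr.tsv")
    lines.append("[reciprocal FDR]")
    if fdr is None or not len(fdr):
        lines.append("stage not run")
    else:
        r = fdr.iloc[0]
        lines.append(f"reciprocal_false_loci={int(r['reciprocal_false_loci'])} "
                     f"called_snps={int(r['called_snps'])} "
                     f"evaluable_loci={int(r['evaluable_loci'])} "
                     f"fdr={r['fdr']:.3g} ({r['denominator']})")
    lines.append("")
    assigns = _read("assignments.tsv")
    lines.append("[gene regions]")
    if assigns is None:
        lines.append("stage not run")
    elif not len(assigns):
        lines.append("no assignments")
    else:
        for region, cnt in assigns.groupby("region").size().items():
            lines.append(f"  {region}: {cnt}")
        lines.append(f"  genes hit: {assigns['gene_id'].nunique()}")
    lines.append("")
    n_calls = (0 if snps is None else len(snps)) + (
        0 if indels is None else len(indels))
    dens = _read("densities.tsv")
    enr = _read("enrichment.tsv")
    if n_calls == 0:
        lines.append("[enrichment]")
        lines.append("zero calls: enrichment omitted")
        lines.append("")
    else:
        lines.append("[polymorphism density]")
        if dens is None or not len(dens):
            lines.append("stage not run")
        else:
            mu = dens["count"].sum() / dens["ext_kb"].sum()
            lines.append(f"mu={mu:.4g} polymorphisms/kb over "
                         f"{len(dens)} extended genes")
            for mult in (2, 3, 10):
                n = int((dens["multiple"] >= mult).sum())
                lines.append(f"  genes >= {mult}x mu: {n}")
        lines.append("")
        lines.append("[enrichment]")
        if enr is None:
            lines.append("stage not run")
        elif not len(enr):
            lines.append("no pathway sets")
        else:
            for _, r in enr.sort_values("p").iterrows():
                lines.append(f"  {r['set']}: N={int(r['N'])} K={int(r['K'])} "
                             f"n={int(r['n'])} k={int(r['k'])} "
                             f"p={r['p']:.3g} q={r['q_bh']:.3g}")
        lines.append("")
    lines.append("[truth-table confusion matrix (SNP sites)]")
    if truth is None or snps is None:
        lines.append("stage not run")
    else:
        tsnp = truth[truth["kind"] == "snp"]
        called = {(str(a), int(p)) for a, p in zip(snps.get("arm", []),
                                                   snps.get("pos", []))}
        is_called = tsnp.apply(
            lambda r: (str(r["arm"]), int(r["pos"])) in called, axis=1)
        exp = tsnp["expected_callable"].astype(bool)
        tp = int((is_called & exp).sum())
        fp = int((is_called & ~exp).sum())
        fn = int((~is_called & exp).sum())
        tn = int((~is_called & ~exp).sum())
        lines.append(f"  called/callable: {tp}   called/not-callable: {fp}")
        lines.append(f"  missed/callable: {fn}   quiet/not-callable: {tn}")
        lines.append(f"  cells sum: {tp + fp + fn + tn} of {len(tsnp)} "
                     f"truth SNP sites")
        if tp + fp:
            lines.append(f"  precision: {tp / (tp + fp):.4g}")
        if tp + fn:
            lines.append(f"  recall (vs truth-callable): {tp / (tp + fn):.4g}")
        ev = _read("evaluable_sites.tsv")
        if ev is not None:
            ev_set = {(str(a), int(p)) for a, p, e in
                      zip(ev["arm"], ev["pos"], ev["evaluable"]) if e}
            is_ev = tsnp.apply(
                lambda r: (str(r["arm"]), int(r["pos"])) in ev_set, axis=1)
            tp_e = int((is_called & exp & is_ev).sum())
            fn_e = int((~is_called & exp & is_ev).sum())
            if tp_e + fn_e:
                lines.append(f"  recall (vs truth-callable & evaluable): "
                             f"{tp_e / (tp_e + fn_e):.4g}")
    lines.append("")
    path = outdir / "report.txt"
    path.write_text("\n".join(lines))
    return path
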