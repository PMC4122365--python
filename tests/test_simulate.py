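"""Generator correctness: founders, Wright-Fisher dynamics, pooling,
sequencing noise, and the annotation substrate."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from poolsweep import pool_io
from poolsweep.annotate import build_extended_index
from poolsweep.simulate import (SeqConfig, SimConfig, Population,
                                deterministic_selection, evolve_replicates,
                                expected_callable, generate_annotation,
                                generate_founders, sample_pool,
                                select_sweep_targets, sequence_pool,
                                simulate_experiment, wright_fisher)


def _cfg(**kw) -> SimConfig:
    base = dict(genome_length=10_000, n_arms=1, pop_size=200, generations=10)
    base.update(kw)
    return SimConfig(**base)


class TestFounders:
    def test_zero_density_gives_reference_only_panel(self, rng):
        panel = generate_founders(_cfg(), 0.0, rng)
        assert len(panel) == 0
        assert set(panel.reference) == {"X"}

    def test_single_carrier_frequency_is_one_over_27(self, rng):
        panel = generate_founders(_cfg(), 5.0, rng)
        single = panel.sites[panel.sites["k"] == 1]
        assert len(single) > 0
        assert np.allclose(single["p0"], 1 / 27)

    def test_deterministic_under_fixed_seed(self):
        a = generate_founders(_cfg(), 5.0, np.random.default_rng(42))
        b = generate_founders(_cfg(), 5.0, np.random.default_rng(42))
        assert a.sites.equals(b.sites)
        assert (a.haplotypes == b.haplotypes).all()
        assert a.reference == b.reference

    def test_empty_genome_rejected(self, rng):
        with pytest.raises(ValueError, match="empty genome"):
            generate_founders(_cfg(genome_length=0), 1.0, rng)

    def test_reference_carries_ancestral_allele(self, rng):
        panel = generate_founders(_cfg(), 5.0, rng)
        for _, r in panel.sites.iterrows():
            assert panel.reference[r["arm"]][r["pos"] - 1] == r["ref"]

    def test_carrier_counts_match_haplotype_matrix(self, rng):
        panel = generate_founders(_cfg(), 5.0, rng)
        assert (panel.haplotypes.sum(axis=0) == panel.sites["k"]).all()


class TestWrightFisher:
    def test_zero_generations_returns_p0_exactly(self, rng):
        p0 = np.array([1 / 27, 0.25, 0.9])
        out = wright_fisher(p0, np.full(3, 400), np.zeros(3), 0, rng)
        assert (out == p0).all()

    def test_neutral_mean_frequency_conserved(self, rng):
        """Martingale property: E[p_G] = p0 under drift alone."""
        n = 1000
        p0 = np.full(n, 0.25)
        out = wright_fisher(p0, np.full(n, 400), np.zeros(n), 50, rng)
        se = out.std(ddof=1) / np.sqrt(n)
        assert abs(out.mean() - 0.25) < 3 * se

    def test_strong_selection_matches_deterministic_limit(self, rng):
        expected = deterministic_selection(0.05, 0.2, 100)
        out = wright_fisher(np.full(50, 0.05), np.full(50, 20_000),
                            np.full(50, 0.2), 100, rng)
        assert np.abs(out - expected).max() < 0.02

    def test_heterozygosity_decays_at_one_over_2n_per_generation(self, rng):
        n, two_n, gens = 20_000, 40, 15
        p0 = np.full(n, 0.5)
        out = wright_fisher(p0, np.full(n, two_n), np.zeros(n), gens, rng)
        het = 2 * out * (1 - out)
        expected = 2 * 0.5 * 0.5 * (1 - 1 / two_n) ** gens
        se = het.std(ddof=1) / np.sqrt(n)
        assert abs(het.mean() - expected) < 3 * se

    def test_non_finite_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="non-finite"):
            wright_fisher(np.array([0.5]), np.array([100]),
                          np.array([np.nan]), 1, rng)


class TestEvolveReplicates:
    def test_control_is_neutral_and_selected_flagged(self, rng):
        panel = generate_founders(_cfg(generations=0), 5.0, rng)
        targets = select_sweep_targets(panel, 3, 0.5, rng)
        cfg = _cfg(generations=0)
        pops, truth = evolve_replicates(panel, cfg, rng, targets=targets)
        assert truth["selected"].sum() == 3
        # generations=0: all final frequencies equal p0 exactly
        for pool in ("C1", "H1", "H2"):
            assert (truth[f"freq_{pool}"] == truth["p0"]).all()

    def test_expected_callable_matches_brute_force(self, rng):
        cfg = _cfg(pop_size=50, generations=40, pool_males=20,
                   pool_females=20)
        panel = generate_founders(cfg, 5.0, rng)
        pops, truth = evolve_replicates(panel, cfg, rng)
        for _, r in truth.iterrows():
            brute = (r["freq_H1"] >= 0.9 and r["freq_H2"] >= 0.9
                     and r["freq_C1"] <= 0.1)
            assert bool(r["expected_callable"]) == brute

    def test_neutral_populations_exchangeable(self, rng):
        cfg = _cfg(genome_length=50_000, pop_size=100, generations=30,
                   pool_males=50, pool_females=50)
        panel = generate_founders(cfg, 10.0, rng)
        pops, _ = evolve_replicates(panel, cfg, rng)
        stat = stats.ks_2samp(pops["C1"].freqs, pops["H1"].freqs)
        assert stat.pvalue > 0.01

    def test_bottleneck_schedule_decays_heterozygosity_per_census(self, rng):
        """With a per-generation census schedule, expected heterozygosity
        decays by the product of (1 - 1/(2N_g)) factors."""
        from poolsweep.simulate import wright_fisher
        schedule = (20, 5, 50, 10, 30)
        copies = np.stack([np.full(20_000, 2 * n) for n in schedule])
        out = wright_fisher(np.full(20_000, 0.5), copies,
                            np.zeros(20_000), len(schedule), rng)
        het = 2 * out * (1 - out)
        expected = 0.5 * np.prod([1 - 1 / (2 * n) for n in schedule])
        se = het.std(ddof=1) / np.sqrt(len(het))
        assert abs(het.mean() - expected) < 3 * se

    def test_schedule_length_must_match_generations(self):
        with pytest.raises(ValueError, match="schedule length"):
            _cfg(generations=5, pop_size_schedule=(100, 100))

    def test_block_linkage_ties_sites_sharing_carriers(self, rng):
        """Without recombination, sites on one arm carried by the same
        founder lineages drift as a unit (identical trajectories)."""
        cfg = _cfg(generations=25, linkage="blocks")
        panel = generate_founders(cfg, 10.0, rng)
        pops, truth = evolve_replicates(panel, cfg, rng)
        sites = panel.sites
        freqs = pops["C1"].freqs
        carriers = {}
        for j in range(len(sites)):
            key = (sites.at[j, "arm"], tuple(panel.haplotypes[:, j]))
            carriers.setdefault(key, []).append(freqs[j])
        shared = [v for v in carriers.values() if len(v) > 1]
        assert shared  # some carrier sets recur at density 10/kb
        for v in shared:
            assert len(set(v)) == 1
        # the neutral martingale still holds lineage-wise
        assert abs(freqs.mean() - sites["p0"].mean()) < 0.1

    def test_unknown_target_rejected(self, rng):
        panel = generate_founders(_cfg(), 5.0, rng)
        with pytest.raises(ValueError, match="not a panel site"):
            evolve_replicates(panel, _cfg(), rng,
                              targets=[("X", 1, 0.5)])


class TestSamplePool:
    def _population(self, freqs, arm_is_x, pop_size=200):
        copies = np.where(arm_is_x, (pop_size // 2) * 3, 2 * pop_size)
        return Population("C1", np.asarray(freqs, float),
                          copies.astype(np.int64), pop_size,
                          np.asarray(arm_is_x))

    def test_x_arm_samples_300_copies(self, rng):
        pop = self._population([0.5], [True])
        # 100 males + 100 females on the X: 2*100 + 100 = 300 copies
        freqs = sample_pool(pop, 100, 100, rng)
        assert (freqs * 300 == np.rint(freqs * 300)).all()

    def test_autosome_samples_400_copies(self, rng):
        pop = self._population([0.5], [False])
        freqs = sample_pool(pop, 100, 100, rng)
        assert (freqs * 400 == np.rint(freqs * 400)).all()

    def test_fixed_site_always_fixed(self, rng):
        pop = self._population([1.0, 0.0], [False, True])
        freqs = sample_pool(pop, 100, 100, rng)
        assert freqs[0] == 1.0 and freqs[1] == 0.0

    def test_pool_larger_than_population_rejected(self, rng):
        pop = self._population([0.5], [False], pop_size=150)
        with pytest.raises(ValueError, match="pool larger"):
            sample_pool(pop, 100, 100, rng)


class TestSequencePool:
    def test_error_free_fixed_pool_all_alt(self, rng):
        cfg = _cfg(genome_length=2000)
        panel = generate_founders(cfg, 5.0, rng, indel_fraction=0.0)
        seq = SeqConfig(mean_depth=20, base_error=0.0)
        out = sequence_pool(np.ones(len(panel)), seq, panel, rng)
        alt_idx = panel.sites["alt"].map({b: i for i, b in
                                          enumerate("ACGT")}).to_numpy()
        counts = np.stack([out[b] for b in "ACGT"], axis=1)
        assert (counts.sum(axis=1) == out["depth"]).all()
        assert (counts[np.arange(len(panel)), alt_idx] == out["depth"]).all()

    def test_depth_is_poisson_with_configured_mean(self, rng):
        cfg = _cfg(genome_length=100_000)
        panel = generate_founders(cfg, 100.0, rng)  # 10^4 sites
        out = sequence_pool(np.zeros(len(panel)), SeqConfig(mean_depth=15),
                            panel, rng)
        d = out["depth"]
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 15) < 3 * se

    def test_allele_fraction_is_binomial_around_pool_frequency(self, rng):
        cfg = _cfg(genome_length=100_000)
        panel = generate_founders(cfg, 100.0, rng, indel_fraction=0.0)
        out = sequence_pool(np.full(len(panel), 0.5),
                            SeqConfig(mean_depth=30, base_error=0.0),
                            panel, rng)
        alt_idx = panel.sites["alt"].map({b: i for i, b in
                                          enumerate("ACGT")}).to_numpy()
        counts = np.stack([out[b] for b in "ACGT"], axis=1)
        keep = out["depth"] > 0
        frac = (counts[np.arange(len(panel)), alt_idx][keep]
                / out["depth"][keep])
        se = frac.std(ddof=1) / np.sqrt(keep.sum())
        assert abs(frac.mean() - 0.5) < 3 * se

    def test_deletion_reads_reduce_base_count_sum(self, rng):
        cfg = _cfg(genome_length=5000)
        panel = generate_founders(cfg, 10.0, rng, indel_fraction=1.0)
        out = sequence_pool(np.full(len(panel), 0.5),
                            SeqConfig(base_error=0.0), panel, rng)
        counts = np.stack([out[b] for b in "ACGT"], axis=1)
        is_del = (panel.sites["kind"] == "del").to_numpy()
        assert (counts.sum(axis=1)[is_del] + out["del"][is_del]
                == out["depth"][is_del]).all()
        assert (out["del_fwd"] + out["del_rev"] == out["del"]).all()


class TestGenerateAnnotation:
    def test_zero_genes_yields_header_only_gff3(self, rng, tmp_path):
        ref, genes, sets = generate_annotation({"X": 10_000}, 0, rng)
        path = tmp_path / "empty.gff3"
        pool_io.write_gff3(genes, {"X": 10_000}, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert all(l.startswith("#") for l in lines)

    def test_cds_translates_without_internal_stops(self, rng):
        """Translate-and-scan oracle over every generated gene."""
        ref, genes, _ = generate_annotation({"X": 60_000, "2L": 60_000},
                                            40, rng)
        from poolsweep.annotate import coding_sequence
        for g in genes:
            protein = str(Seq(coding_sequence(g, ref)).translate())
            assert protein.startswith("M")
            assert protein.endswith("*")
            assert "*" not in protein[:-1]
            assert g.cds_length() % 3 == 0

    def test_gff3_round_trip_identity(self, rng, tmp_path):
        ref, genes, _ = generate_annotation({"X": 60_000}, 20, rng)
        path = tmp_path / "genes.gff3"
        pool_io.write_gff3(genes, {"X": 60_000}, path)
        back, arm_lengths = pool_io.read_gff3(path)
        assert arm_lengths == {"X": 60_000}
        assert sorted(back, key=lambda g: g.gene_id) == sorted(
            genes, key=lambda g: g.gene_id)

    def test_infeasible_packing_rejected(self, rng):
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_annotation({"X": 5_000}, 40, rng)

    def test_pathway_sets_partition_genes(self, rng):
        _, genes, sets = generate_annotation({"X": 60_000}, 20, rng,
                                             n_pathways=4)
        assert len(sets) == 4
        union = set().union(*sets.values())
        assert union == {g.gene_id for g in genes}
        assert sum(len(s) for s in sets.values()) == len(genes)


class TestSimulateExperiment:
    def test_artifacts_are_consistent(self, rng):
        cfg = SimConfig(genome_length=30_000, n_arms=2, pop_size=200,
                        generations=20)
        res = simulate_experiment(cfg, SeqConfig(), rng, n_genes=10,
                                  n_targets=3, s=0.3, n_indel_targets=1)
        assert len(res.table) == len(res.panel) == len(res.truth)
        assert len(res.targets) == 4
        assert res.truth["selected"].sum() == 4
        build_extended_index(res.genes, arm_lengths=cfg.arm_lengths)

    def test_pool_constraint_enforced(self):
        with pytest.raises(ValueError, match="pool larger"):
            SimConfig(pop_size=150)
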