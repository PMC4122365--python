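"""Variant-scan correctness: evaluability, SNP/indel criteria, reciprocal
FDR arithmetic, and homopolymer flagging against independent oracles."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from poolsweep.pool_io import TABLE_COLUMNS, PoolSiteTable
from poolsweep.scan import (CallerConfig, IndelCall, QualityThresholds,
                            call_indels, call_snps, estimate_fdr_reciprocal,
                            evaluable_mask, flag_homopolymer,
                            reciprocal_false_loci)

from conftest import make_site, make_table


class TestEvaluableMask:
    def test_all_thresholds_met(self):
        table = make_table([make_site(
            "2L", 1, "A",
            {"A": 12, "baseq": 25, "bestq": 41},
            {"A": 15, "baseq": 30, "bestq": 45},
            {"A": 11, "baseq": 22, "bestq": 50})])
        mask, frac = evaluable_mask(table)
        assert mask[0] and frac == {"2L": 1.0}

    def test_single_pool_failure_suffices(self):
        table = make_table([make_site(
            "2L", 1, "A",
            {"A": 9},              # C1 depth 9 < 10
            {"A": 15}, {"A": 11})])
        mask, frac = evaluable_mask(table)
        assert not mask[0] and frac == {"2L": 0.0}

    def test_matches_per_site_recomputation(self, rng):
        rows = []
        for i in range(10_000):
            pools = []
            for _ in range(3):
                pools.append({"A": int(rng.integers(0, 25)),
                              "baseq": int(rng.integers(0, 45)),
                              "bestq": int(rng.integers(0, 70))})
            rows.append(make_site("2L", i + 1, "A", *pools))
        table = make_table(rows)
        thr = QualityThresholds()
        mask, _ = evaluable_mask(table, thr)
        df = table.df
        for i in range(len(df)):
            expect = all(
                df.loc[i, f"{p}_depth"] >= thr.min_depth
                and df.loc[i, f"{p}_baseq"] >= thr.min_baseq
                and df.loc[i, f"{p}_bestq"] >= thr.min_bestq
                for p in ("C1", "H1", "H2"))
            assert mask[i] == expect


class TestCallSnps:
    def test_worked_example_is_called_with_expected_frequencies(self):
        table = make_table([make_site(
            "2L", 100, "A",
            {"A": 28, "T": 2}, {"T": 19, "A": 1}, {"T": 10})])
        mask, _ = evaluable_mask(table)
        calls = call_snps(table, mask)
        assert len(calls) == 1
        c = calls[0]
        assert (c.h_allele, c.c_consensus) == ("T", "A")
        assert c.freq_H1 == pytest.approx(0.95)
        assert c.freq_H2 == pytest.approx(1.0)
        assert c.freq_C1 == pytest.approx(2 / 30)
        assert c.h_identity

    def test_085_fixation_is_below_threshold(self):
        table = make_table([make_site(
            "2L", 100, "A",
            {"A": 30}, {"T": 17, "A": 3}, {"T": 10})])
        mask, _ = evaluable_mask(table)
        assert call_snps(table, mask) == []

    def test_site_outside_mask_never_called(self):
        table = make_table([make_site(
            "2L", 100, "A", {"A": 30}, {"T": 20}, {"T": 10})])
        assert call_snps(table, np.array([False])) == []

    def test_discordant_h_alleles_emitted_without_identity(self):
        table = make_table([make_site(
            "2L", 100, "A", {"A": 30}, {"T": 20}, {"G": 12})])
        mask, _ = evaluable_mask(table)
        calls = call_snps(table, mask)
        assert len(calls) == 1 and not calls[0].h_identity
        assert (calls[0].h_allele, calls[0].h2_allele) == ("T", "G")
        assert call_snps(table, mask,
                         CallerConfig(require_h_identity=True)) == []

    def test_h_allele_matching_control_consensus_not_called(self):
        # control majority T: a T fixed in H pools is no difference
        table = make_table([make_site(
            "2L", 100, "A", {"T": 30}, {"T": 20}, {"T": 12})])
        mask, _ = evaluable_mask(table)
        assert call_snps(table, mask) == []


class TestCallerOracleEquivalence:
    def test_small_grid_matches_independent_checker(self):
        """All (depth <= 6)^3 two-allele count configurations; the full
        depth <= 12 enumeration runs in the acceptance suite."""
        pairs = [(d, t) for d in range(7) for t in range(d + 1)]
        rows = []
        keys = []
        for dc, tc in pairs:
            for d1, t1 in pairs:
                for d2, t2 in pairs:
                    keys.append(((dc, d1, d2), (tc, t1, t2)))
        # depth <= 6 never passes the mask; drop the mask to exercise the
        # criteria themselves on this small grid
        for i, ((dc, d1, d2), (tc, t1, t2)) in enumerate(keys):
            rows.append(make_site(
                "2L", i + 1, "A",
                {"A": dc - tc, "T": tc}, {"A": d1 - t1, "T": t1},
                {"A": d2 - t2, "T": t2}))
        table = make_table(rows)
        mask = np.ones(len(rows), dtype=bool)
        called = {(c.arm, c.pos) for c in call_snps(table, mask)}
        cfg = CallerConfig()
        for i, (depths, alts) in enumerate(keys):
            # mimic mask-off by treating depth rule as passed
            (dc, d1, d2), (tc, t1, t2) = depths, alts
            f = lambda t, d: t / d if d else 0.0
            cons = "T" if tc > dc - tc else "A"
            expect = (f(t1, d1) >= 0.9 and f(t2, d2) >= 0.9
                      and cons != "T" and f(tc, dc) <= 0.1)
            assert (("2L", i + 1) in called) == expect, (depths, alts)


class TestCallIndels:
    def _site(self, h_sup=(6, 5), c_sup=0, h_depth=12, c_depth=12,
              kind="del"):
        f, r = h_sup
        h = {"A": h_depth - f - r if kind != "del" else 0,
             f"{kind}_fwd": f, f"{kind}_rev": r,
             "depth": h_depth}
        c = {"A": c_depth - c_sup, f"{kind}_fwd": c_sup, "depth": c_depth}
        return make_table([make_site("2L", 50, "A", c, h, dict(h))])

    def test_both_strand_support_typed_star(self):
        table = self._site(h_sup=(6, 5))
        calls = call_indels(table)
        assert len(calls) == 1 and calls[0].maq_type == "*"
        assert calls[0].support_H1 == pytest.approx(11 / 12)

    def test_same_strand_pair_typed_plus(self):
        table = self._site(h_sup=(11, 0))
        calls = call_indels(table)
        assert len(calls) == 1 and calls[0].maq_type == "+"

    def test_low_coverage_not_called(self):
        table = self._site(h_sup=(5, 4), h_depth=9)
        assert call_indels(table) == []

    def test_control_support_boundary(self):
        table = self._site(c_sup=1)
        assert call_indels(table) == []
        calls = call_indels(
            table, config=CallerConfig(control_absence_max_reads=1))
        assert len(calls) == 1 and calls[0].control_support_reads == 1

    def test_support_below_fixation_not_called(self):
        # 8/12 deletion support < 90%
        table = self._site(h_sup=(4, 4))
        assert call_indels(table) == []


class TestReciprocalFdr:
    def _reciprocal_table(self):
        return make_table([
            # H1 fixed T, H2 all-ref: a reciprocal false locus
            make_site("2L", 10, "A", {"A": 20}, {"T": 19, "A": 1},
                      {"A": 15}),
            # concordant selection signal: not reciprocal
            make_site("2L", 20, "A", {"A": 20}, {"T": 15}, {"T": 15}),
        ])

    def test_worked_example_rate(self):
        table = self._reciprocal_table()
        mask = np.ones(2, dtype=bool)
        est = estimate_fdr_reciprocal(table, mask, CallerConfig(),
                                      called_snps=2514)
        assert est.reciprocal_false_loci == 1
        assert est.fdr == pytest.approx(1 / 2514)
        assert float(f"{est.fdr:.1e}") == 4.0e-04  # two significant figures

    def test_zero_reciprocal_loci_gives_zero_fdr(self):
        table = make_table([make_site("2L", 10, "A", {"A": 20}, {"T": 15},
                                      {"T": 15})])
        est = estimate_fdr_reciprocal(table, np.ones(1, bool),
                                      CallerConfig(), called_snps=5)
        assert est.fdr == 0.0

    def test_undefined_fdr_raises(self):
        table = self._reciprocal_table()
        with pytest.raises(ZeroDivisionError, match="undefined FDR"):
            estimate_fdr_reciprocal(table, np.ones(2, bool), CallerConfig(),
                                    called_snps=0)

    def test_locus_counted_once_even_if_both_directions(self):
        # H1 fixed T / H2 all-ref counts once although H2 is also "rare T"
        table = self._reciprocal_table()
        assert reciprocal_false_loci(table, np.ones(2, bool)) == 1

    def test_evaluable_denominator(self):
        table = self._reciprocal_table()
        est = estimate_fdr_reciprocal(table, np.ones(2, bool), CallerConfig(),
                                      called_snps=1,
                                      denominator="evaluable")
        assert est.fdr == pytest.approx(1 / 2)


class TestHomopolymerFlag:
    def _del_call(self, pos, base="A"):
        return IndelCall("X", pos, base, "del", base, "*", 1.0, 1.0, 0)

    def test_run_of_six_flagged_at_min_run_five(self):
        ref = {"X": "CGTAAAAAAGT"}  # run of 6 A at positions 4-9
        out = flag_homopolymer([self._del_call(5)], ref, min_run=5)
        assert out[0].homopolymer_flag

    def test_run_of_two_not_flagged(self):
        ref = {"X": "CGTAATCGGT"}
        out = flag_homopolymer([self._del_call(5)], ref, min_run=5)
        assert not out[0].homopolymer_flag

    def test_position_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="outside reference"):
            flag_homopolymer([self._del_call(99)], {"X": "ACGT"})

    def test_matches_regex_run_oracle_on_random_contexts(self, rng):
        """10^4 random contexts vs an independent regular-expression
        run-length scanner."""
        min_run = 5
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seq = "".join(rng.choice(bases, p=[0.4, 0.2, 0.2, 0.2], size=500))
            ref = {"X": seq}
            calls = []
            for _ in range(500):
                pos = int(rng.integers(1, len(seq) + 1))
                calls.append(IndelCall("X", pos, seq[pos - 1], "del",
                                       seq[pos - 1], "*", 1.0, 1.0, 0))
            out = flag_homopolymer(calls, ref, min_run=min_run)
            # oracle: spans of >= min_run identical bases; a deletion is
            # flagged iff its base's run touches pos or an adjacent index
            runs = [(m.start(), m.end(), m.group(1)) for m in
                    re.finditer(r"(.)\1{%d,}" % (min_run - 1), seq)]
            for call, flagged in zip(calls, out):
                p0 = call.pos - 1
                expect = any(s - 1 <= p0 <= e and b == call.seq
                             for s, e, b in runs)
                assert flagged.homopolymer_flag == expect, (call.pos, seq)


class TestDeterminism:
    def test_identical_table_and_config_give_identical_calls(self, rng,
                                                             tmp_path):
        from poolsweep import pool_io
        from poolsweep.simulate import SeqConfig, SimConfig, simulate_experiment
        cfg = SimConfig(genome_length=20_000, pop_size=200, generations=30)
        res = simulate_experiment(cfg, SeqConfig(), rng, n_targets=3, s=0.5)
        mask, _ = evaluable_mask(res.table)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        pool_io.write_calls(call_snps(res.table, mask), p1, "tsv")
        pool_io.write_calls(call_snps(res.table, mask), p2, "tsv")
        assert p1.read_bytes() == p2.read_bytes()


@given(fix=st.integers(1, 20), rare=st.integers(0, 20))
def test_caller_config_threshold_ordering(fix, rare):
    """rare_threshold must stay strictly below fix_threshold."""
    fix_f, rare_f = fix / 20, rare / 20
    if rare_f < fix_f:
        CallerConfig(fix_threshold=fix_f, rare_threshold=rare_f)
    else:
        with pytest.raises(ValueError):
            CallerConfig(fix_threshold=fix_f, rare_threshold=rare_f)
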