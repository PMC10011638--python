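"""Instrument selection: significance filter, LD clumping, F screening."""

import itertools

import numpy as np
import pytest

from tsmr import LDMatrix, SummaryStatSet, clump, f_statistic, filter_significant, screen_weak
from tsmr.instruments import InstrumentSet

from conftest import make_variant


def candidate_set(records):
    return SummaryStatSet("exp", "continuous", records)


class TestSignificanceFilter:
    def test_strict_comparison_on_mixed_pvalues(self):
        ds = candidate_set([
            make_variant("rs1", pval=1e-9, pos=1),
            make_variant("rs2", ea="C", oa="T", pval=1e-7, pos=2),
            make_variant("rs3", ea="G", oa="A", pval=1e-8, pos=3),
        ])
        kept = filter_significant(ds, 5e-8)
        assert [r.rsid for r in kept] == ["rs1", "rs3"]

    def test_all_above_threshold_gives_empty_set(self):
        ds = candidate_set([make_variant("rs1", pval=0.5)])
        assert len(filter_significant(ds, 5e-8)) == 0

    def test_threshold_one_keeps_everything(self, small_sumstats):
        assert len(filter_significant(small_sumstats, 1.0)) == len(small_sumstats)

    def test_idempotent(self, small_sumstats):
        once = filter_significant(small_sumstats, 5e-8)
        twice = filter_significant(once, 5e-8)
        assert [r.rsid for r in once] == [r.rsid for r in twice]


class TestFStatistic:
    @pytest.mark.parametrize("beta, se, expected", [
        (0.1, 0.02, 25.0), (0.0, 0.5, 0.0), (-0.3, 0.1, 9.0)])
    def test_formula(self, beta, se, expected):
        rec = make_variant(beta=beta, se=se)
        assert f_statistic(rec) == pytest.approx(expected)


def brute_force_clump(records, ld, r2_threshold, window_kb):
    """Exhaustive reference of the greedy rule, recomputed from scratch each pick."""
    remaining = list(records)
    kept = []
    while remaining:
        index = min(remaining, key=lambda r: (r.pval, r.pos, r.rsid))
        kept.append(index.rsid)
        remaining = [
            r for r in remaining
            if r.rsid != index.rsid and not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_kb * 1000
                and ld.lookup(index.rsid, r.rsid) >= r2_threshold
            )
        ]
    return kept


class TestClumping:
    def test_correlated_nearby_pair_keeps_best_pvalue(self):
        recs = [make_variant("rs1", pval=1e-10, pos=100_000),
                make_variant("rs2", ea="C", oa="T", pval=1e-9, pos=105_000)]
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        out = clump(candidate_set(recs), ld, r2_threshold=0.001, window_kb=10_000)
        assert [r.rsid for r in out] == ["rs1"]
        assert ("rs2", "dropped:clumped-with:rs1") in out.provenance

    def test_different_chromosomes_both_kept(self):
        recs = [make_variant("rs1", pval=1e-10, chrom="1", pos=100),
                make_variant("rs2", ea="C", oa="T", pval=1e-9, chrom="2", pos=100)]
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        out = clump(candidate_set(recs), ld, 0.001, 10_000)
        assert len(out) == 2

    def test_matches_brute_force_reference_on_random_instances(self, rng):
        for trial in range(10):
            j = 10
            rsids = [f"rs{i}" for i in range(j)]
            recs = [
                make_variant(rsids[i], ea="A", oa="G",
                             pval=float(rng.uniform(1e-12, 1e-6)),
                             chrom=str(rng.integers(1, 3)),
                             pos=int(rng.integers(1, 5_000_000)))
                for i in range(j)
            ]
            a = rng.uniform(0, 1, size=(j, j))
            r2 = (a + a.T) / 2
            np.fill_diagonal(r2, 1.0)
            ld = LDMatrix(rsids, r2)
            ours = [r.rsid for r in clump(candidate_set(recs), ld, 0.3, 1_000)]
            ref = brute_force_clump(recs, ld, 0.3, 1_000)
            assert ours == ref

    def test_invariant_to_input_row_order(self, rng):
        recs = [make_variant(f"rs{i}", pval=float(rng.uniform(1e-12, 1e-6)),
                             chrom="1", pos=int(rng.integers(1, 2_000_000)))
                for i in range(6)]
        a = rng.uniform(0, 1, size=(6, 6))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix([r.rsid for r in recs], r2)
        baseline = [r.rsid for r in clump(candidate_set(recs), ld, 0.3, 1_000)]
        for perm in itertools.islice(itertools.permutations(recs), 0, 24, 5):
            assert [r.rsid for r in clump(candidate_set(list(perm)), ld, 0.3, 1_000)] == baseline

    def test_kept_set_internally_valid(self, rng):
        recs = [make_variant(f"rs{i}", pval=float(rng.uniform(1e-12, 1e-6)),
                             chrom="1", pos=int(rng.integers(1, 3_000_000)))
                for i in range(12)]
        a = rng.uniform(0, 1, size=(12, 12))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix([r.rsid for r in recs], r2)
        out = clump(candidate_set(recs), ld, 0.3, 1_000)
        for x, y in itertools.combinations(out.records, 2):
            violates = (x.chrom == y.chrom and abs(x.pos - y.pos) <= 1_000_000
                        and ld.lookup(x.rsid, y.rsid) >= 0.3)
            assert not violates

    def test_missing_variant_is_hard_error_naming_rsid(self):
        recs = [make_variant("rs1"), make_variant("rs9", ea="C", oa="T", pos=2_000)]
        ld = LDMatrix.identity(["rs1"])
        with pytest.raises(KeyError, match="rs9"):
            clump(candidate_set(recs), ld, 0.001, 10_000)
        out = clump(candidate_set(recs), ld, 0.001, 10_000, permissive=True)
        assert len(out) == 2


class TestWeakScreening:
    def test_zero_threshold_is_identity(self):
        instr = InstrumentSet([make_variant("rs1"), make_variant("rs2", ea="C", oa="T")])
        assert len(screen_weak(instr, 0.0)) == 2

    def test_threshold_drops_weak(self):
        instr = InstrumentSet([
            make_variant("rs1", beta=0.1, se=0.02),    # F = 25
            make_variant("rs2", ea="C", oa="T", beta=0.04, se=0.0141),  # F ~ 8
            make_variant("rs3", ea="G", oa="A", beta=0.11, se=0.02),    # F ~ 30
        ])
        kept = screen_weak(instr, 10.0)
        assert [r.rsid for r in kept] == ["rs1", "rs3"]
        assert ("rs2", "dropped:weak-instrument") in kept.provenance

    def test_all_weak_warns_and_empties(self):
        instr = InstrumentSet([make_variant("rs1", beta=0.01, se=0.02)])
        with pytest.warns(UserWarning, match="below F"):
            out = screen_weak(instr, 10.0)
        assert len(out) == 0

    def test_f_range_reported(self):
        instr = InstrumentSet([make_variant("rs1", beta=0.1, se=0.02),
                               make_variant("rs2", ea="C", oa="T", beta=0.3, se=0.05)])
        lo, hi = instr.f_range()
        assert lo == pytest.approx(25.0) and hi == pytest.approx(36.0)


class TestLDMatrixIO:
    def test_round_trip(self, tmp_path, rng):
        a = rng.uniform(0, 1, size=(4, 4))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix([f"rs{i}" for i in range(4)], r2)
        back = LDMatrix.read(ld.write(tmp_path / "ld.tsv"))
        assert back.rsids == ld.rsids
        np.testing.assert_allclose(back.r2, ld.r2)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            LDMatrix(["a", "b"], np.array([[0.5, 0.1], [0.1, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1.0, 0.3], [0.1, 1.0]]))
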