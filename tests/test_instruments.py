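import numpy as np
import pandas as pd
import pytest

from mrscan import (BlockLDProvider, MatrixLDProvider, PairTableLDProvider,
                    clump, exclude_mhc, filter_significant, find_proxy,
                    load_ld, select_instruments, simulate_ld)
from mrscan.errors import InputError, ParameterError
from mrscan.instruments import apply_proxies

from conftest import make_record, make_set


def grid_set(pvals, positions=None, chrom="1", role="exposure"):
    positions = positions or [1000 * (i + 1) for i in range(len(pvals))]
    return make_set(
        [make_record(snp_id=f"rs{i + 1}", chrom=chrom, pos=positions[i],
                     pval=p) for i, p in enumerate(pvals)],
        role=role)


class TestLDProviders:
    def test_matrix_contract(self):
        labels = ["rs1", "rs2", "rs3"]
        m = pd.DataFrame([[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]],
                         index=labels, columns=labels)
        ld = MatrixLDProvider(m)
        assert ld.r2("rs1", "rs1") == 1.0
        assert ld.r2("rs1", "rs2") == ld.r2("rs2", "rs1") == 0.5
        assert ld.r2("rs1", "rs_unknown") == 0.0
        assert not ld.known("rs1", "rs_unknown")

    def test_matrix_rejects_asymmetry(self):
        labels = ["rs1", "rs2"]
        m = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=labels, columns=labels)
        with pytest.raises(InputError):
            MatrixLDProvider(m)

    def test_pair_table(self):
        df = pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs2"], "r2": [0.7],
                           "aligned": [True]})
        ld = PairTableLDProvider(df)
        assert ld.r2("rs2", "rs1") == 0.7
        assert ld.r2("rs1", "rs3") == 0.0
        nb = ld.neighbors("rs1", 0.5)
        assert nb[0].snp_id == "rs2" and nb[0].aligned is True

    def test_load_ld_dispatch(self, tmp_path):
        pair = tmp_path / "pairs.tsv"
        pair.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.9\n")
        assert isinstance(load_ld(pair), PairTableLDProvider)
        mat = tmp_path / "matrix.tsv"
        mat.write_text("snp\trs1\trs2\nrs1\t1.0\t0.3\nrs2\t0.3\t1.0\n")
        ld = load_ld(mat)
        assert isinstance(ld, MatrixLDProvider)
        assert ld.r2("rs1", "rs2") == pytest.approx(0.3)
        # file-backed matrix carries no orientation info
        assert ld.neighbors("rs1", 0.1)[0].aligned is None

    def test_block_provider_symmetric_unit_diag(self):
        ld, placement = simulate_ld([(3, 0.9), (2, 0.5)])
        snps = list(placement["snp_id"])
        for a in snps:
            assert ld.r2(a, a) == 1.0
            for b in snps:
                assert ld.r2(a, b) == ld.r2(b, a)
                assert 0.0 <= ld.r2(a, b) <= 1.0


class TestFilterSignificant:
    def test_threshold_forced_selection(self):
        s = grid_set([1e-9, 1e-7, 0.2])
        kept = filter_significant(s, 5e-8)
        assert kept.snp_ids == ("rs1",)

    def test_vacuous_threshold(self):
        s = grid_set([0.5, 0.99, 1e-3])
        assert len(filter_significant(s, 1.0)) == 3

    def test_empty_input(self):
        s = make_set([], role="exposure")
        assert len(filter_significant(s, 5e-8)) == 0

    def test_strict_inequality(self):
        s = grid_set([5e-8])
        assert len(filter_significant(s, 5e-8)) == 0

    def test_bad_threshold(self):
        with pytest.raises(ParameterError):
            filter_significant(grid_set([0.5]), 0.0)


class TestExcludeMHC:
    def test_inside_region_removed(self):
        s = grid_set([1e-9], positions=[30_000_000], chrom="6")
        assert len(exclude_mhc(s)) == 0

    def test_boundaries_closed(self):
        s = make_set([
            make_record(snp_id="rs1", chrom="6", pos=26_000_000),
            make_record(snp_id="rs2", chrom="6", pos=34_000_000),
            make_record(snp_id="rs3", chrom="6", pos=25_999_999),
            make_record(snp_id="rs4", chrom="6", pos=34_000_001),
        ])
        kept = exclude_mhc(s)
        assert kept.snp_ids == ("rs3", "rs4")

    def test_other_chromosome_kept(self):
        s = grid_set([1e-9], positions=[30_000_000], chrom="7")
        assert len(exclude_mhc(s)) == 1

    def test_chr_prefix_label(self):
        s = grid_set([1e-9], positions=[30_000_000], chrom="6")
        assert len(exclude_mhc(s, chrom="chr6")) == 0

    def test_commutes_with_filter_significant(self):
        s = make_set([
            make_record(snp_id=f"rs{i}", chrom="6" if i % 2 else "1",
                        pos=20_000_000 + i * 5_000_000, pval=10.0**-i)
            for i in range(1, 8)
        ])
        a = exclude_mhc(filter_significant(s, 1e-3))
        b = filter_significant(exclude_mhc(s), 1e-3)
        assert a.snp_ids == b.snp_ids


def greedy_oracle(records, r2_fn, r2_max, window_bp):
    """Independent recursive statement of the greedy clumping rule."""
    pool = sorted(records, key=lambda r: (r.pval, r.snp_id))
    if not pool:
        return []
    top, rest = pool[0], pool[1:]
    survivors = [
        r for r in rest
        if not (r.chrom == top.chrom and abs(r.pos - top.pos) <= window_bp
                and r2_fn(top.snp_id, r.snp_id) >= r2_max)
    ]
    return [top.snp_id] + greedy_oracle(survivors, r2_fn, r2_max, window_bp)


class TestClump:
    def test_two_snps_high_ld(self):
        s = grid_set([1e-10, 1e-9])
        ld, _ = simulate_ld([(2, 0.5)])
        sel = clump(s, ld, r2_max=0.001, window_bp=10_000_000)
        assert sel.kept == ["rs1"]
        assert sel.removed == [("rs2", "clumped_by:rs1")]

    def test_boundary_below_threshold_both_kept(self):
        s = grid_set([1e-10, 1e-9])
        ld, _ = simulate_ld([(2, 0.0005)])
        sel = clump(s, ld, r2_max=0.001)
        assert sorted(sel.kept) == ["rs1", "rs2"]

    def test_boundary_at_threshold_removed(self):
        s = grid_set([1e-10, 1e-9])
        ld, _ = simulate_ld([(2, 0.001)])
        sel = clump(s, ld, r2_max=0.001)
        assert sel.kept == ["rs1"]

    def test_window_limits_removal(self):
        s = grid_set([1e-10, 1e-9], positions=[1000, 20_000_000])
        ld, _ = simulate_ld([(2, 0.9)])
        sel = clump(s, ld, r2_max=0.001, window_bp=10_000_000)
        assert sorted(sel.kept) == ["rs1", "rs2"]

    def test_conservation_invariant(self, rng):
        s = grid_set(list(rng.uniform(size=8)))
        ld, _ = simulate_ld([(4, 0.8), (4, 0.0)])
        sel = clump(s, ld, r2_max=0.1)
        assert set(sel.kept) | sel.removed_ids == set(s.snp_ids)
        assert not set(sel.kept) & sel.removed_ids

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        pvals = rng.uniform(1e-12, 1e-6, size=n)
        positions = sorted(rng.integers(1, 5_000_000, size=n).tolist())
        s = grid_set(pvals.tolist(), positions=positions)
        r2 = rng.uniform(0, 0.02, size=(n, n))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        labels = [f"rs{i + 1}" for i in range(n)]
        ld = MatrixLDProvider(pd.DataFrame(r2, index=labels, columns=labels))
        sel = clump(s, ld, r2_max=0.01, window_bp=3_000_000)
        expected = greedy_oracle(list(s), ld.r2, 0.01, 3_000_000)
        assert sel.kept == expected

    def test_row_order_invariance(self, rng):
        pvals = rng.uniform(size=6).tolist()
        positions = [1000 * (i + 1) for i in range(6)]
        recs = [make_record(snp_id=f"rs{i + 1}", pos=positions[i], pval=pvals[i])
                for i in range(6)]
        ld, _ = simulate_ld([(3, 0.9), (3, 0.9)])
        sel_fwd = clump(make_set(recs), ld, r2_max=0.5)
        sel_rev = clump(make_set(recs[::-1]), ld, r2_max=0.5)
        assert sel_fwd.kept == sel_rev.kept

    def test_greedy_stability(self, rng):
        """Removing a SNP outside the kept set leaves the kept set unchanged."""
        pvals = rng.uniform(size=6).tolist()
        s = grid_set(pvals)
        ld, _ = simulate_ld([(6, 0.9)])
        sel = clump(s, ld, r2_max=0.5)
        for dropped in sel.removed_ids:
            sub = s.subset([snp for snp in s.snp_ids if snp != dropped])
            assert clump(sub, ld, r2_max=0.5).kept == sel.kept

    def test_bad_r2_max(self):
        ld, _ = simulate_ld([(2, 0.5)])
        with pytest.raises(ParameterError):
            clump(grid_set([0.5, 0.5]), ld, r2_max=0.0)


class TestFindProxy:
    def test_max_r2_selected(self):
        ld = BlockLDProvider({"rsA": 0, "rsB": 0, "rsC": 0}, {0: 0.9})
        outcome = make_set(
            [make_record(snp_id=s, pos=1000) for s in ("rsB", "rsC")],
            role="outcome")
        # distinct r2: build via pair table instead
        df = pd.DataFrame({"snp_a": ["rsA", "rsA"], "snp_b": ["rsB", "rsC"],
                           "r2": [0.95, 0.85], "aligned": [True, True]})
        ld = PairTableLDProvider(df)
        assert find_proxy("rsA", outcome, ld, 0.8) == ("rsB", 0.95)

    def test_none_when_no_candidate(self):
        df = pd.DataFrame({"snp_a": ["rsA"], "snp_b": ["rsB"], "r2": [0.5],
                           "aligned": [True]})
        ld = PairTableLDProvider(df)
        outcome = make_set([make_record(snp_id="rsB", pos=1000)], role="outcome")
        assert find_proxy("rsA", outcome, ld, 0.8) is None

    def test_tie_breaks_lexicographically(self):
        df = pd.DataFrame({"snp_a": ["rsA", "rsA"], "snp_b": ["rsC", "rsB"],
                           "r2": [0.9, 0.9], "aligned": [True, True]})
        ld = PairTableLDProvider(df)
        outcome = make_set(
            [make_record(snp_id=s, pos=1000) for s in ("rsB", "rsC")],
            role="outcome")
        # enumeration over both candidate orders gives the same winner
        assert find_proxy("rsA", outcome, ld, 0.8) == ("rsB", 0.9)

    def test_unaligned_candidates_rejected(self):
        df = pd.DataFrame({"snp_a": ["rsA"], "snp_b": ["rsB"], "r2": [0.99]})
        ld = PairTableLDProvider(df)  # no aligned column -> orientation unknown
        outcome = make_set([make_record(snp_id="rsB", pos=1000)], role="outcome")
        assert find_proxy("rsA", outcome, ld, 0.8) is None


class TestSelectInstruments:
    def test_full_pipeline_bookkeeping(self):
        records = [
            make_record(snp_id="rs1", chrom="1", pos=1_000, pval=1e-10),
            make_record(snp_id="rs2", chrom="1", pos=2_000, pval=1e-9),
            make_record(snp_id="rs3", chrom="6", pos=30_000_000, pval=1e-12),
            make_record(snp_id="rs4", chrom="1", pos=3_000, pval=0.5),
        ]
        s = make_set(records)
        ld = BlockLDProvider({"rs1": 0, "rs2": 0}, {0: 0.9})
        kept, sel = select_instruments(s, ld=ld, p_threshold=5e-8)
        assert kept.snp_ids == ("rs1",)
        reasons = dict(sel.removed)
        assert reasons["rs4"] == "above_p_threshold"
        assert reasons["rs3"] == "mhc_region"
        assert reasons["rs2"] == "clumped_by:rs1"

    def test_missing_in_outcome_no_proxy(self):
        s = make_set([make_record(snp_id="rs1", pval=1e-10)])
        outcome = make_set([make_record(snp_id="rs2", pos=2000)], role="outcome")
        ld = BlockLDProvider({"rs1": 0}, {0: 0.9})
        kept, sel = select_instruments(s, outcome=outcome, ld=ld)
        assert len(kept) == 0
        assert ("rs1", "missing_in_outcome_no_proxy") in sel.removed

    def test_proxy_substitution(self):
        s = make_set([make_record(snp_id="rs1", pval=1e-10)])
        outcome = make_set(
            [make_record(snp_id="rs2", pos=2000, beta=0.07, se=0.015)],
            role="outcome")
        ld = BlockLDProvider({"rs1": 0, "rs2": 0}, {0: 0.95})
        kept, sel = select_instruments(s, outcome=outcome, ld=ld)
        assert kept.snp_ids == ("rs1",)
        assert sel.proxies == [("rs1", "rs2", 0.95)]
        out2 = apply_proxies(outcome, sel.proxies, s)
        assert "rs1" in out2 and "rs2" not in out2
        assert out2["rs1"].beta == pytest.approx(0.07)
        assert out2["rs1"].effect_allele == s["rs1"].effect_allele
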