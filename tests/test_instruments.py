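"""Instrument strength algebra, clumping, proxies, and harmonization."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpipe import gwas_io
from mrpipe.errors import DomainError
from mrpipe.gwas_io import GwasDataset, LDReference
from mrpipe.instruments import (
    COMPLEMENT, SelectionConfig, align_alleles, compute_r2_f, find_proxy,
    harmonize, select_instruments,
)


def _dataset(rows, name="exp", **kw):
    df = pd.DataFrame(rows, columns=[
        "rsid", "chrom", "pos", "effect_allele", "other_allele",
        "beta", "se", "pval", "eaf", "n"])
    return GwasDataset(trait_name=name, table=df, **kw)


class TestComputeR2F:
    def test_zero_effect_gives_zero(self):
        r2, f = compute_r2_f(0.0, 0.01, 0.3, 1000)
        assert r2 == 0.0 and f == 0.0

    def test_hand_computed_value(self):
        # exact-fraction oracle for the printed R2/F formulas:
        # R2 = 2 b^2 q(1-q) / (2 b^2 q(1-q) + 2 se^2 N q(1-q)), F = R2 (N-2)/(1-R2)
        b, se, q, n = Fraction(1, 10), Fraction(1, 100), Fraction(1, 4), 10_000
        num = 2 * b**2 * q * (1 - q)
        den = num + 2 * se**2 * n * q * (1 - q)
        r2_exact = num / den
        f_exact = r2_exact * (n - 2) / (1 - r2_exact)
        assert float(r2_exact) == pytest.approx(1 / 101, rel=1e-15)
        assert float(f_exact) == pytest.approx(99.98, rel=1e-12)
        r2, f = compute_r2_f(0.1, 0.01, 0.25, 10_000)
        assert r2 == pytest.approx(float(r2_exact), rel=1e-12)
        assert f == pytest.approx(float(f_exact), rel=1e-12)

    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        se=st.floats(1e-4, 0.5),
        n=st.integers(10, 10**6),
        eaf1=st.floats(0.01, 0.99),
        eaf2=st.floats(0.01, 0.99),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_eaf_invariance_and_sign_invariance(self, beta, se, n, eaf1, eaf2):
        r2a, fa = compute_r2_f(beta, se, eaf1, n)
        r2b, fb = compute_r2_f(beta, se, eaf2, n)
        r2c, fc = compute_r2_f(-beta, se, eaf1, n)
        assert r2a == pytest.approx(r2b, rel=1e-9, abs=1e-15)
        assert fa == pytest.approx(fb, rel=1e-9, abs=1e-12)
        assert (r2a, fa) == (r2c, fc)

    def test_f_increases_with_signal_to_noise(self):
        fs = [compute_r2_f(b, 0.01, 0.3, 5000)[1] for b in (0.01, 0.02, 0.05, 0.1)]
        assert fs == sorted(fs) and fs[0] < fs[-1]

    def test_small_n_rejected(self):
        with pytest.raises(DomainError):
            compute_r2_f(0.1, 0.01, 0.3, 2)


class TestClumping:
    def _ld(self, panel_rows, pairs):
        panel = pd.DataFrame(panel_rows, columns=["rsid", "chrom", "pos"])
        return LDReference.from_pairs(panel, pairs)

    def test_correlated_nearby_snp_removed(self):
        exp = _dataset([
            ["rs1", "1", 100_000, "A", "G", 0.1, 0.01, 1e-8, 0.3, 1000],
            ["rs2", "1", 110_000, "A", "G", 0.1, 0.01, 1e-6, 0.3, 1000],
        ])
        ld = self._ld([["rs1", "1", 100_000], ["rs2", "1", 110_000]], [("rs1", "rs2", 0.5)])
        assert select_instruments(exp, ld) == ["rs1"]

    def test_different_chromosomes_both_kept(self):
        exp = _dataset([
            ["rs1", "1", 100_000, "A", "G", 0.1, 0.01, 1e-8, 0.3, 1000],
            ["rs2", "2", 100_000, "A", "G", 0.1, 0.01, 1e-6, 0.3, 1000],
        ])
        ld = self._ld([["rs1", "1", 100_000], ["rs2", "2", 100_000]], [("rs1", "rs2", 0.9)])
        assert select_instruments(exp, ld) == ["rs1", "rs2"]

    def test_far_apart_same_chromosome_both_kept(self):
        # joint rule: discard needs BOTH r2 >= threshold AND within the window
        exp = _dataset([
            ["rs1", "1", 1_000_000, "A", "G", 0.1, 0.01, 1e-8, 0.3, 1000],
            ["rs2", "1", 3_000_000, "A", "G", 0.1, 0.01, 1e-6, 0.3, 1000],
        ])
        ld = self._ld([["rs1", "1", 1_000_000], ["rs2", "1", 3_000_000]],
                      [("rs1", "rs2", 0.9)])
        assert select_instruments(exp, ld) == ["rs1", "rs2"]

    def test_matches_brute_force_on_block_structure(self):
        # 20 SNPs in 4 LD blocks; oracle is an independently written O(n^2)
        # greedy clumper over fully sorted candidates
        rng = np.random.default_rng(42)
        rows, panel, pairs = [], [], []
        for b in range(4):
            for j in range(5):
                rsid = f"rs{b}_{j}"
                pos = 1_000_000 + b * 5_000_000 + j * 10_000
                rows.append([rsid, "1", pos, "A", "G", 0.1, 0.01,
                             float(rng.uniform(1e-9, 1e-5)), 0.3, 1000])
                panel.append([rsid, "1", pos])
        for b in range(4):
            ids = [f"rs{b}_{j}" for j in range(5)]
            for i in range(5):
                for j in range(i + 1, 5):
                    pairs.append((ids[i], ids[j], 0.6))
        exp = _dataset(rows)
        ld = self._ld(panel, pairs)
        cfg = SelectionConfig()
        got = select_instruments(exp, ld, cfg)

        cand = sorted(rows, key=lambda r: (r[7], r[1], r[2], r[0]))
        kept = []
        for r in cand:
            ok = True
            for k in kept:
                same_chr = r[1] == k[1]
                near = abs(r[2] - k[2]) <= cfg.clump_kb * 1000
                if same_chr and near and ld.r2(r[0], k[0]) >= cfg.clump_r2:
                    ok = False
            if ok:
                kept.append(r)
        assert got == [k[0] for k in kept]
        assert len(got) == 4  # one per block

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = [[f"rs{i}", str(1 + i % 3), 1_000_000 + i * 200_000, "A", "G",
                 0.1, 0.01, float(rng.uniform(1e-9, 1e-5)), 0.3, 1000] for i in range(12)]
        panel = [[r[0], r[1], r[2]] for r in rows]
        ld = self._ld(panel, [(rows[i][0], rows[i + 1][0], 0.3) for i in range(0, 10, 2)])
        a = select_instruments(_dataset(rows), ld)
        b = select_instruments(_dataset(rows[::-1]), ld)
        assert a == b

    def test_no_candidate_returns_empty(self):
        exp = _dataset([["rs1", "1", 100, "A", "G", 0.1, 0.01, 0.5, 0.3, 1000]])
        ld = self._ld([["rs1", "1", 100]], [])
        assert select_instruments(exp, ld) == []


class TestFindProxy:
    def _outcome(self, rsids):
        return _dataset(
            [[r, "1", 100 + i, "A", "G", 0.1, 0.01, 0.5, 0.3, 1000]
             for i, r in enumerate(rsids)], name="out",
        )

    def test_max_r2_wins(self):
        ld = LDReference.from_pairs(
            pd.DataFrame({"rsid": ["q", "a", "b"], "chrom": ["1"] * 3,
                          "pos": [100, 200, 300]}),
            [("q", "a", 0.85), ("q", "b", 0.95)])
        assert find_proxy("q", self._outcome(["a", "b"]), ld) == "b"

    def test_below_threshold_returns_none(self):
        ld = LDReference.from_pairs(
            pd.DataFrame({"rsid": ["q", "a"], "chrom": ["1", "1"], "pos": [100, 200]}),
            [("q", "a", 0.79)])
        assert find_proxy("q", self._outcome(["a"]), ld) is None

    def test_tie_broken_by_position(self):
        ld = LDReference.from_pairs(
            pd.DataFrame({"rsid": ["q", "far", "near"], "chrom": ["1"] * 3,
                          "pos": [100, 900, 150]}),
            [("q", "far", 0.9), ("q", "near", 0.9)])
        assert find_proxy("q", self._outcome(["far", "near"]), ld) == "near"


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, eaf_exp=0.3, eaf_out=0.3,
              beta_out=-0.05):
        exp = _dataset([["rs1", "1", 100, *exp_alleles, 0.1, 0.01, 1e-8, eaf_exp, 10_000]])
        out = _dataset([["rs1", "1", 100, *out_alleles, beta_out, 0.02, 0.01,
                         eaf_out, 200_000]], name="out")
        return exp, out

    def test_swapped_alleles_flip_outcome_beta(self):
        exp, out = self._pair(("A", "G"), ("G", "A"))
        res = harmonize(exp, out, ["rs1"])
        assert len(res) == 1
        assert res[0].beta_out == pytest.approx(0.05)

    def test_strand_complement_recovered(self):
        # exposure A/G vs outcome T/C is the same variant on the other strand
        exp, out = self._pair(("A", "G"), ("T", "C"))
        res = harmonize(exp, out, ["rs1"])
        assert len(res) == 1 and res[0].beta_out == pytest.approx(-0.05)

    def test_palindrome_intermediate_frequency_eliminated(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), eaf_exp=0.50, eaf_out=0.50)
        res = harmonize(exp, out, ["rs1"])
        assert len(res) == 0 and res.dropped["rs1"] == "palindromic"

    def test_palindrome_resolved_by_concordant_frequencies(self):
        exp, out = self._pair(("A", "T"), ("T", "A"), eaf_exp=0.2, eaf_out=0.8)
        res = harmonize(exp, out, ["rs1"])
        assert len(res) == 1 and res[0].beta_out == pytest.approx(0.05)

    def test_incompatible_allele_sets_eliminated(self):
        exp, out = self._pair(("A", "G"), ("A", "C"))
        res = harmonize(exp, out, ["rs1"])
        assert len(res) == 0 and res.dropped["rs1"] == "incompatible"

    def test_full_allele_case_table(self):
        # enumerate all 4x4 ordered outcome allele pairs against exposure A/G;
        # truth table written out before implementation: action per case
        expected = {}
        for ea in "ACGT":
            for oa in "ACGT":
                if ea == oa:
                    continue
                if (ea, oa) == ("A", "G"):
                    expected[(ea, oa)] = "keep"
                elif (ea, oa) == ("G", "A"):
                    expected[(ea, oa)] = "flip"
                elif (ea, oa) == ("T", "C"):  # complement of A/G
                    expected[(ea, oa)] = "keep"
                elif (ea, oa) == ("C", "T"):
                    expected[(ea, oa)] = "flip"
                else:
                    expected[(ea, oa)] = "drop_incompatible"
        for (ea, oa), want in expected.items():
            got = align_alleles("A", "G", ea, oa, 0.3, 0.3)
            assert got == want, f"outcome {ea}/{oa}: wanted {want}, got {got}"

    def test_weak_instruments_dropped_and_f_floor_holds(self):
        rows_exp, rows_out = [], []
        for i, beta in enumerate((0.1, 0.02, 0.005)):
            rows_exp.append([f"rs{i}", "1", 100 + i, "A", "G", beta, 0.01, 1e-8, 0.3, 1000])
            rows_out.append([f"rs{i}", "1", 100 + i, "A", "G", 0.05, 0.02, 0.01, 0.3, 1000])
        res = harmonize(_dataset(rows_exp), _dataset(rows_out, name="out"),
                        [f"rs{i}" for i in range(3)])
        assert all(i.f_stat > 10 for i in res)
        assert "weak-F" in res.dropped.values()

    def test_exposure_increasing_orientation(self):
        exp = _dataset([["rs1", "1", 100, "A", "G", -0.1, 0.01, 1e-8, 0.3, 10_000]])
        out = _dataset([["rs1", "1", 100, "A", "G", 0.05, 0.02, 0.01, 0.3, 1000]], name="out")
        res = harmonize(exp, out, ["rs1"])
        ins = res[0]
        assert ins.beta_exp == pytest.approx(0.1)
        assert ins.beta_out == pytest.approx(-0.05)
        assert (ins.effect_allele, ins.other_allele) == ("G", "A")
        assert ins.eaf_exp == pytest.approx(0.7)

    def test_missing_eaf_makes_snp_ineligible(self):
        exp = _dataset([["rs1", "1", 100, "A", "G", 0.1, 0.01, 1e-8, np.nan, 10_000]])
        out = _dataset([["rs1", "1", 100, "A", "G", 0.05, 0.02, 0.01, 0.3, 1000]], name="out")
        res = harmonize(exp, out, ["rs1"])
        assert len(res) == 0 and res.dropped["rs1"] == "missing-eaf"

    def test_involution_safe(self):
        # re-harmonizing already-aligned data changes nothing
        exp, out = self._pair(("A", "G"), ("G", "A"))
        first = harmonize(exp, out, ["rs1"])[0]
        exp2 = _dataset([["rs1", "1", 100, first.effect_allele, first.other_allele,
                          first.beta_exp, first.se_exp, first.pval_exp,
                          first.eaf_exp, first.n_exp]])
        out2 = _dataset([["rs1", "1", 100, first.effect_allele, first.other_allele,
                          first.beta_out, first.se_out, first.pval_out,
                          first.eaf_exp, 200_000]], name="out")
        second = harmonize(exp2, out2, ["rs1"])[0]
        assert second.beta_exp == pytest.approx(first.beta_exp)
        assert second.beta_out == pytest.approx(first.beta_out)
        assert (second.effect_allele, second.other_allele) == (
            first.effect_allele, first.other_allele)

    def test_proxy_substitution(self):
        exp = _dataset([
            ["rs1", "1", 100, "A", "G", 0.1, 0.01, 1e-8, 0.3, 10_000],
            ["rsP", "1", 150, "A", "G", 0.09, 0.01, 1e-7, 0.3, 10_000],
        ])
        out = _dataset([["rsP", "1", 150, "A", "G", 0.05, 0.02, 0.01, 0.3, 1000]], name="out")
        ld = LDReference.from_pairs(
            pd.DataFrame({"rsid": ["rs1", "rsP"], "chrom": ["1", "1"], "pos": [100, 150]}),
            [("rs1", "rsP", 0.9)])
        proxy = find_proxy("rs1", out, ld)
        assert proxy == "rsP"
        res = harmonize(exp, out, ["rs1"], proxies={"rs1": proxy}, ld=ld)
        assert len(res) == 1
        ins = res[0]
        assert ins.is_proxy and ins.rsid == "rsP" and ins.source_rsid == "rs1"
        assert ins.proxy_r2 == pytest.approx(0.9)
        assert ins.beta_exp == pytest.approx(0.09)  # proxy's own exposure effect
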