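import numpy as np
import pytest

from mrkit.estimators import ivw
from mrkit.harmonize import harmonized_set_from_arrays
from mrkit.instruments import InstrumentSet
from mrkit.mvmr import MVMRInput, build_mvmr_input, mvmr_ivw
from mrkit.sumstats import SummaryStatRecord, SummaryStatTable

from conftest import make_record, make_table


def minput(beta_exp, beta_out, se_out, names=None):
    beta_exp = np.asarray(beta_exp, dtype=float)
    k, m = beta_exp.shape
    return MVMRInput(
        exposure_names=names or [f"e{i}" for i in range(m)],
        snp_ids=[f"rs{i}" for i in range(k)],
        beta_exp=beta_exp,
        se_exp=np.full((k, m), 0.01),
        beta_out=np.asarray(beta_out, dtype=float),
        se_out=np.asarray(se_out, dtype=float),
    )


class TestMvmrIvw:
    def test_single_exposure_reduces_to_univariable_ivw(self, rng):
        k = 20
        be = rng.normal(0.2, 0.05, k)
        so = rng.uniform(0.01, 0.03, k)
        bo = 0.4 * be + rng.normal(0, so)
        uni = ivw(harmonized_set_from_arrays(be, np.full(k, 0.01), bo, so))
        multi = mvmr_ivw(minput(be[:, None], bo, so))
        assert multi.beta[0] == pytest.approx(uni.beta, abs=1e-12)
        assert multi.se[0] == pytest.approx(uni.se, abs=1e-12)

    def test_two_exposure_recovery(self):
        errs1, errs2 = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            k = 100
            bx = rng.normal(0.2, 0.05, (k, 2))
            so = np.full(k, 0.01)
            bo = 0.5 * bx[:, 0] + 0.0 * bx[:, 1] + rng.normal(0, 0.01, k)
            res = mvmr_ivw(minput(bx, bo, so))
            errs1.append(res.beta[0] - 0.5)
            errs2.append(res.beta[1] - 0.0)
        assert abs(np.mean(errs1)) < 2 * np.std(errs1) / np.sqrt(30)
        assert abs(np.mean(errs2)) < 2 * np.std(errs2) / np.sqrt(30)

    def test_duplicated_exposure_column_raises_naming_pair(self, rng):
        be = rng.normal(0.2, 0.05, 10)
        x = np.column_stack([be, be])
        with pytest.raises(ValueError, match="e0~e1"):
            mvmr_ivw(minput(x, 0.5 * be, np.full(10, 0.01)))

    def test_permuting_columns_permutes_coefficients(self, rng):
        k = 50
        bx = rng.normal(0.2, 0.05, (k, 3))
        so = np.full(k, 0.01)
        bo = bx @ np.array([0.5, -0.2, 0.1]) + rng.normal(0, 0.01, k)
        res = mvmr_ivw(minput(bx, bo, so, names=["a", "b", "c"]))
        perm = [2, 0, 1]
        res_p = mvmr_ivw(minput(bx[:, perm], bo, so, names=["c", "a", "b"]))
        assert res_p.beta == pytest.approx(res.beta[perm], abs=1e-10)

    def test_orthogonal_instruments_approach_univariable(self, rng):
        # Each SNP instruments exactly one exposure; conditional estimates
        # should approach the univariable ones.
        k = 60
        bx = np.zeros((k, 2))
        bx[:30, 0] = rng.normal(0.2, 0.02, 30)
        bx[30:, 1] = rng.normal(0.2, 0.02, 30)
        so = np.full(k, 0.01)
        bo = bx @ np.array([0.5, -0.3]) + rng.normal(0, 0.01, k)
        res = mvmr_ivw(minput(bx, bo, so))
        uni0 = ivw(harmonized_set_from_arrays(bx[:30, 0], np.full(30, 0.01), bo[:30], so[:30]))
        uni1 = ivw(harmonized_set_from_arrays(bx[30:, 1], np.full(30, 0.01), bo[30:], so[30:]))
        assert res.beta[0] == pytest.approx(uni0.beta, abs=0.02)
        assert res.beta[1] == pytest.approx(uni1.beta, abs=0.02)

    def test_k_not_exceeding_m_is_hard_error(self):
        with pytest.raises(ValueError):
            minput(np.ones((2, 2)), np.ones(2), np.ones(2))


class TestBuildInput:
    def _tables(self, n=10, effect=(0.5, -0.3), seed=0):
        rng = np.random.default_rng(seed)
        recs_a, recs_b, recs_y = [], [], []
        for i in range(n):
            base = make_record(f"rs{i}", chrom=str(i % 22 + 1), pos=(i // 22 + 1) * 20_000_000)
            ba = float(rng.normal(0.2, 0.02))
            bb = float(rng.normal(0.15, 0.02))
            import dataclasses

            recs_a.append(dataclasses.replace(base, beta=ba, pval=1e-12))
            recs_b.append(dataclasses.replace(base, beta=bb, pval=1e-10))
            recs_y.append(dataclasses.replace(
                base, beta=effect[0] * ba + effect[1] * bb, se=0.02, pval=0.5))
        return (
            make_table(recs_a, "A"), make_table(recs_b, "B"), make_table(recs_y, "Y"),
        )

    def test_disjoint_instrument_union(self):
        ta, tb, ty = self._tables(10)
        iset_a = InstrumentSet("A", list(ta.records)[:5], 5e-8)
        iset_b = InstrumentSet("B", list(tb.records)[5:], 5e-8)
        inp = build_mvmr_input({"A": iset_a, "B": iset_b}, {"A": ta, "B": tb}, ty)
        assert inp.k == 10 and inp.m == 2

    def test_snp_missing_from_one_table_dropped_and_audited(self):
        ta, tb, ty = self._tables(10)
        tb_short = tb.subset([r.snp_id for r in tb.records if r.snp_id != "rs3"])
        iset_a = InstrumentSet("A", list(ta.records), 5e-8)
        iset_b = InstrumentSet("B", list(tb_short.records), 5e-8)
        inp = build_mvmr_input({"A": iset_a, "B": iset_b}, {"A": ta, "B": tb_short}, ty)
        assert inp.k == 9
        assert ("rs3", "missing_from_exposure:B") in inp.dropped

    def test_matrices_match_hand_assembly(self):
        ta, tb, ty = self._tables(8)
        iset_a = InstrumentSet("A", list(ta.records), 5e-8)
        iset_b = InstrumentSet("B", list(tb.records), 5e-8)
        inp = build_mvmr_input({"A": iset_a, "B": iset_b}, {"A": ta, "B": tb}, ty)
        for row, sid in enumerate(inp.snp_ids):
            assert inp.beta_exp[row, 0] == ta.get(sid).beta
            assert inp.beta_exp[row, 1] == tb.get(sid).beta
            assert inp.beta_out[row] == ty.get(sid).beta

    def test_end_to_end_recovers_joint_effects(self):
        ta, tb, ty = self._tables(40, effect=(0.5, -0.3))
        iset_a = InstrumentSet("A", list(ta.records), 5e-8)
        iset_b = InstrumentSet("B", list(tb.records), 5e-8)
        inp = build_mvmr_input({"A": iset_a, "B": iset_b}, {"A": ta, "B": tb}, ty)
        res = mvmr_ivw(inp)
        assert res.beta[list(inp.exposure_names).index("A")] == pytest.approx(0.5, abs=0.05)
        assert res.beta[list(inp.exposure_names).index("B")] == pytest.approx(-0.3, abs=0.05)
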