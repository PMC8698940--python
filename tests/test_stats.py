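import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ductmorph as dm


def make_table(values: dict, time=90.0):
    rows = [dict(sample_id=sid, time_h=time, total_tips=v)
            for sid, v in values.items()]
    return pd.DataFrame(rows)


def two_group_design(ids_a, ids_b, paired=False, times=(90.0,)):
    return dm.GroupDesign(
        groups={"A": list(ids_a), "B": list(ids_b)},
        metric="total_tips", times=times,
        pairing=dict(zip(ids_a, ids_b)) if paired else None,
    )


class TestSummarize:
    def test_mean_sem_closed_form(self):
        tab = make_table({"a0": 3.0, "a1": 5.0, "a2": 7.0, "b0": 1.0, "b1": 1.0})
        des = two_group_design(["a0", "a1", "a2"], ["b0", "b1"])
        s = dm.summarize(tab, des).set_index("group")
        assert s.loc["A", "mean"] == 5.0
        assert s.loc["A", "sem"] == pytest.approx(2.0 / np.sqrt(3))
        assert s.loc["B", "sem"] == 0.0

    def test_single_sample_group_rejected_by_design(self):
        with pytest.raises(ValueError):
            dm.GroupDesign(groups={"A": ["x"], "B": ["y", "z"]})


class TestCompareTwo:
    def test_identical_groups_tie(self):
        tab = make_table({f"a{i}": 10.0 for i in range(4)} | {f"b{i}": 10.0 for i in range(4)})
        des = two_group_design([f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
        res = dm.compare_two(tab, des).iloc[0]
        assert res.statistic == 0.0 and res.p_raw == 1.0 and res.tie

    def test_paired_and_unpaired_agree_on_identity_pairing(self):
        rng = np.random.default_rng(1)
        vals_a = {f"a{i}": float(v) for i, v in enumerate(rng.normal(10, 2, 6))}
        vals_b = {f"b{i}": float(v) for i, v in enumerate(rng.normal(12, 2, 6))}
        tab = make_table(vals_a | vals_b)
        means_p = dm.compare_two(tab, two_group_design(list(vals_a), list(vals_b), paired=True)).iloc[0]
        means_u = dm.compare_two(tab, two_group_design(list(vals_a), list(vals_b))).iloc[0]
        assert means_p.mean_a == means_u.mean_a
        assert means_p.test.startswith("paired")

    def test_bonferroni_adjustment_over_time_grid(self):
        rng = np.random.default_rng(2)
        rows = []
        for t in (10.0, 20.0, 30.0):
            for i in range(5):
                rows.append(dict(sample_id=f"a{i}", time_h=t, total_tips=float(rng.normal(10, 1))))
                rows.append(dict(sample_id=f"b{i}", time_h=t, total_tips=float(rng.normal(11, 1))))
        tab = pd.DataFrame(rows)
        des = two_group_design([f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)],
                               times=(10.0, 20.0, 30.0))
        res = dm.compare_two(tab, des)
        assert np.allclose(res.p_adj, np.minimum(1.0, res.p_raw * 3))
        assert ((res.p_adj >= res.p_raw) & (res.p_adj <= 1.0)).all()

    def test_pairing_must_be_bijection(self):
        with pytest.raises(ValueError, match="bijection"):
            dm.GroupDesign(
                groups={"A": ["a0", "a1"], "B": ["b0", "b1"]},
                pairing={"a0": "b0", "a1": "b0"},
            )


class TestCompareMulti:
    def test_identical_trio_f_zero(self):
        vals = {f"{g}{i}": 5.0 for g in "abc" for i in range(3)}
        tab = make_table(vals)
        des = dm.GroupDesign(
            groups={g: [f"{g}{i}" for i in range(3)] for g in "abc"},
            metric="total_tips", times=(90.0,), control="a",
        )
        res = dm.compare_multi(tab, des)
        assert (res.anova_F == 0.0).all() and res.tie.all()

    def test_posthoc_against_control_with_bonferroni(self):
        rng = np.random.default_rng(3)
        vals = {f"{g}{i}": float(rng.normal(m, 1))
                for g, m in zip("abc", (10, 10, 15)) for i in range(5)}
        tab = make_table(vals)
        des = dm.GroupDesign(
            groups={g: [f"{g}{i}" for i in range(5)] for g in "abc"},
            metric="total_tips", times=(90.0,), control="a",
        )
        res = dm.compare_multi(tab, des)
        assert set(res.group) == {"b", "c"}
        assert np.allclose(res.p_adj, np.minimum(1.0, res.p_raw * 2))


class TestInvariance:
    @given(seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_result_invariant_to_group_label_order(self, seed):
        rng = np.random.default_rng(seed)
        vals_a = {f"a{i}": float(v) for i, v in enumerate(rng.normal(10, 2, 5))}
        vals_b = {f"b{i}": float(v) for i, v in enumerate(rng.normal(13, 2, 5))}
        tab = make_table(vals_a | vals_b)
        r1 = dm.compare_two(tab, dm.GroupDesign(
            groups={"A": list(vals_a), "B": list(vals_b)},
            metric="total_tips", times=(90.0,))).iloc[0]
        r2 = dm.compare_two(tab, dm.GroupDesign(
            groups={"B": list(vals_b), "A": list(vals_a)},
            metric="total_tips", times=(90.0,))).iloc[0]
        assert r1.p_raw == pytest.approx(r2.p_raw)
        assert r1.statistic == pytest.approx(-r2.statistic)
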