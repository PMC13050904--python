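import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chcscreen.coding import (
    hc_summaries,
    mean_receptivity_per_hc,
    mean_response_per_hc,
    rank_hcs,
    receptivity,
    subfamily_sum,
)
from chcscreen.expression import ExpressionTable, SubfamilyMap
from chcscreen.matrix import ResponseMatrix


def _matrix(grid, receptors=None, hcs=None):
    grid = np.asarray(grid, dtype=float)
    receptors = receptors or [f"R{i}" for i in range(grid.shape[0])]
    hcs = hcs or [f"H{j}" for j in range(grid.shape[1])]
    return ResponseMatrix(mean=pd.DataFrame(grid, index=receptors, columns=hcs))


class TestSubfamilySum:
    def test_members_sum_cellwise(self):
        m = _matrix([[10.0], [20.0]], hcs=["C28"])
        subs = SubfamilyMap({"R0": "V", "R1": "V"})
        grid = subfamily_sum(m, subs)
        assert grid.loc["V", "C28"] == 30.0

    def test_missing_member_cell_contributes_nothing(self):
        m = _matrix([[10.0], [np.nan]], hcs=["C28"])
        grid = subfamily_sum(m, SubfamilyMap({"R0": "V", "R1": "V"}))
        assert grid.loc["V", "C28"] == 10.0

    def test_single_member_subfamily_is_identity(self):
        m = _matrix([[10.0, np.nan]])
        grid = subfamily_sum(m, SubfamilyMap({"R0": "E"}))
        assert grid.loc["E", "H0"] == 10.0
        assert math.isnan(grid.loc["E", "H1"])

    def test_unmapped_receptor_is_named_in_error(self):
        m = _matrix([[1.0]])
        with pytest.raises(ValueError, match="R0"):
            subfamily_sum(m, SubfamilyMap({}))

    def test_subfamily_totals_match_receptor_totals(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(-20, 80, (6, 5))
        grid[rng.random((6, 5)) < 0.3] = np.nan
        m = _matrix(grid)
        subs = SubfamilyMap({f"R{i}": "VEH"[i % 3] for i in range(6)})
        by_sub = subfamily_sum(m, subs).sum(axis=0, min_count=1)
        by_rec = m.mean.sum(axis=0, min_count=1)
        pd.testing.assert_series_equal(by_sub, by_rec, check_names=False)


class TestMeanPerHc:
    def test_denominator_counts_tested_only(self):
        m = _matrix([[10.0], [20.0], [np.nan]], hcs=["C28"])
        out = mean_response_per_hc(m)
        assert out.loc[0, "mean_response"] == 15.0
        assert out.loc[0, "n_tested"] == 2

    def test_untested_hc_stays_missing(self):
        m = _matrix([[np.nan], [np.nan]], hcs=["C28"])
        out = mean_response_per_hc(m)
        assert out.loc[0, "n_tested"] == 0
        assert math.isnan(out.loc[0, "mean_response"])


class TestReceptivity:
    expr = ExpressionTable.from_mapping({"R0": 2.0, "R1": None, "R2": 0.0})

    def test_weighting_and_sign(self):
        m = _matrix([[10.0], [5.0], [-4.0]], hcs=["C28"])
        rec = receptivity(m, self.expr)
        assert rec.values.loc["R0", "C28"] == 20.0
        assert rec.values.loc["R2", "C28"] == 0.0  # zero FPKM zeroes, sign kept

    def test_missing_fpkm_excludes_receptor_entirely(self):
        m = _matrix([[10.0], [5.0], [-4.0]], hcs=["C28"])
        rec = receptivity(m, self.expr)
        assert rec.excluded == ("R1",)
        assert "R1" not in rec.values.index
        out = mean_receptivity_per_hc(rec)
        assert out.loc[0, "n_tested"] == 2  # denominator after exclusion

    def test_negative_receptivity_preserved(self):
        m = _matrix([[-10.0]], receptors=["R0"], hcs=["C28"])
        rec = receptivity(m, self.expr)
        assert rec.values.loc["R0", "C28"] == -20.0

    def test_uniform_fpkm_scales_mean_response(self):
        rng = np.random.default_rng(5)
        grid = rng.uniform(-10, 60, (4, 3))
        grid[0, 1] = np.nan
        m = _matrix(grid)
        expr = ExpressionTable.from_mapping({f"R{i}": 7.0 for i in range(4)})
        resp = mean_response_per_hc(m)["mean_response"]
        rcpt = mean_receptivity_per_hc(receptivity(m, expr))["mean_receptivity"]
        assert np.allclose(rcpt, 7.0 * resp, equal_nan=True)

    def test_scale_equivariance_of_rankings(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.uniform(0, 60, (4, 5)))
        fpkm = {f"R{i}": float(rng.uniform(1, 50)) for i in range(4)}
        s1 = hc_summaries(m, ExpressionTable.from_mapping(fpkm))
        s2 = hc_summaries(
            m, ExpressionTable.from_mapping({k: 3.0 * v for k, v in fpkm.items()})
        )
        assert np.allclose(
            3.0 * s1["mean_receptivity"], s2["mean_receptivity"]
        )
        assert s1["rank_by_receptivity"].tolist() == s2["rank_by_receptivity"].tolist()

    def test_missing_data_consistency(self):
        rng = np.random.default_rng(8)
        grid = rng.uniform(-10, 60, (5, 4))
        grid[rng.random((5, 4)) < 0.3] = np.nan
        m = _matrix(grid)
        expr = ExpressionTable.from_mapping(
            {f"R{i}": (None if i == 2 else 5.0) for i in range(5)}
        )
        n_resp = mean_response_per_hc(m)["n_tested"]
        n_rcpt = mean_receptivity_per_hc(receptivity(m, expr))["n_tested"]
        assert (n_resp >= n_rcpt).all()


class TestRanking:
    def _summaries(self, vals):
        return pd.DataFrame(
            {"hydrocarbon": list(vals), "mean_response": list(vals.values())}
        )

    def test_descending_top_k(self):
        top = rank_hcs(self._summaries({"A": 3.0, "B": 5.0, "C": 4.0}), k=2)
        assert top["hydrocarbon"].tolist() == ["B", "C"]

    def test_tie_broken_alphabetically(self):
        top = rank_hcs(self._summaries({"B": 5.0, "A": 5.0}), k=1)
        assert top["hydrocarbon"].tolist() == ["A"]

    def test_k_larger_than_available_warns(self):
        with pytest.warns(UserWarning, match="only 2"):
            top = rank_hcs(self._summaries({"A": 1.0, "B": 2.0}), k=5)
        assert len(top) == 2

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="rank by"):
            rank_hcs(self._summaries({"A": 1.0}), by="kurtosis")


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_aggregates_match_bruteforce_on_small_matrices(data):
    """All aggregation rules equal an explicit-loop recomputation on random
    matrices up to 5x5 with missing cells."""
    n_r = data.draw(st.integers(1, 5))
    n_h = data.draw(st.integers(1, 5))
    cells = data.draw(
        st.lists(
            st.one_of(st.none(), st.floats(-50, 100, width=32)),
            min_size=n_r * n_h,
            max_size=n_r * n_h,
        )
    )
    grid = np.array(
        [np.nan if c is None else float(c) for c in cells], dtype=float
    ).reshape(n_r, n_h)
    receptors = [f"R{i}" for i in range(n_r)]
    hcs = [f"H{j}" for j in range(n_h)]
    m = _matrix(grid, receptors, hcs)
    labels = data.draw(
        st.lists(st.sampled_from(["V", "E", "9-exon"]), min_size=n_r, max_size=n_r)
    )
    subs = SubfamilyMap(dict(zip(receptors, labels)))
    fpkm_vals = data.draw(
        st.lists(
            st.one_of(st.none(), st.floats(0, 50, width=32)),
            min_size=n_r,
            max_size=n_r,
        )
    )
    expr = ExpressionTable.from_mapping(
        {r: (None if v is None else float(v)) for r, v in zip(receptors, fpkm_vals)}
    )

    # brute-force subfamily sums
    grid_sub = subfamily_sum(m, subs)
    for sub in sorted(set(labels)):
        for j, hc in enumerate(hcs):
            vals = [
                grid[i, j]
                for i in range(n_r)
                if labels[i] == sub and not math.isnan(grid[i, j])
            ]
            expected = sum(vals) if vals else np.nan
            got = grid_sub.loc[sub, hc]
            assert (math.isnan(got) and math.isnan(expected)) or got == pytest.approx(
                expected, abs=1e-6
            )

    # brute-force per-HC means
    out = mean_response_per_hc(m)
    for j, hc in enumerate(hcs):
        vals = [grid[i, j] for i in range(n_r) if not math.isnan(grid[i, j])]
        assert out.loc[j, "n_tested"] == len(vals)
        if vals:
            assert out.loc[j, "mean_response"] == pytest.approx(
                sum(vals) / len(vals), abs=1e-6
            )
        else:
            assert math.isnan(out.loc[j, "mean_response"])

    # brute-force receptivity means (after FPKM exclusion)
    rec = receptivity(m, expr)
    kept = [r for r, v in zip(receptors, fpkm_vals) if v is not None]
    assert list(rec.values.index) == kept
    out_r = mean_receptivity_per_hc(rec)
    for j, hc in enumerate(hcs):
        vals = [
            grid[i, j] * float(fpkm_vals[i])
            for i in range(n_r)
            if fpkm_vals[i] is not None and not math.isnan(grid[i, j])
        ]
        assert out_r.loc[j, "n_tested"] == len(vals)
        if vals:
            assert out_r.loc[j, "mean_receptivity"] == pytest.approx(
                sum(vals) / len(vals), abs=1e-4
            )
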