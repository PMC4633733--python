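"""Bump-hunting caller: elementary operations against hand/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lscsig import (BumpHunter, DataError, bh_adjust, cluster_probes,
                    find_bumps, probe_group_difference, smooth_differences,
                    summarize_dmrs)
from lscsig.io import DMRecord


def _manifest(positions, chrom="chr1"):
    return pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions,
        "context": "open_sea", "snp_flag": False,
    })


class TestGroupDifference:
    def test_simple_means(self):
        beta = pd.DataFrame({"a1": [0.8], "a2": [0.8], "b1": [0.2], "b2": [0.2]},
                            index=["cg1"])
        d = probe_group_difference(beta, ["a1", "a2"], ["b1", "b2"])
        assert d.loc["cg1"] == pytest.approx(0.6)

    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.random(5)
        beta = pd.DataFrame({s: vals for s in ["a1", "a2", "b1", "b2"]},
                            index=[f"cg{i}" for i in range(5)])
        assert np.allclose(probe_group_difference(beta, ["a1", "a2"], ["b1", "b2"]), 0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        beta = pd.DataFrame(rng.random((20, 6)),
                            index=[f"cg{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(6)])
        g1, g2 = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        got = probe_group_difference(beta, g1, g2)
        for probe in beta.index:  # independent per-probe re-computation
            want = (sum(beta.loc[probe, s] for s in g1) / 3
                    - sum(beta.loc[probe, s] for s in g2) / 3)
            assert got.loc[probe] == pytest.approx(want)

    def test_missing_sample_errors(self):
        beta = pd.DataFrame({"a": [0.5], "b": [0.5], "c": [0.1], "d": [0.1]}, index=["cg1"])
        with pytest.raises(DataError, match="missing"):
            probe_group_difference(beta, ["a", "nope"], ["c", "d"])


class TestClustering:
    def test_maxgap_splits(self):
        cl = cluster_probes(_manifest([100, 400, 5000]), maxgap=500)
        assert cl.tolist() == [0, 0, 1]

    def test_extreme_maxgaps(self):
        m = _manifest([100, 400, 5000])
        assert len(set(cluster_probes(m, maxgap=10 ** 9))) == 1
        assert len(set(cluster_probes(m, maxgap=0))) == 3

    def test_clusters_never_span_chromosomes(self):
        m = pd.concat([_manifest([100, 200], "chr1"),
                       _manifest([250, 300], "chr2")], ignore_index=True)
        cl = cluster_probes(m, maxgap=10 ** 6)
        assert cl[1] != cl[2]


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        pos = np.array([0, 100, 200, 300])
        cl = np.zeros(4, dtype=int)
        out = smooth_differences(np.full(4, 0.2), pos, cl, window_bp=150)
        assert np.allclose(out, 0.2)

    def test_spike_running_mean(self):
        # window covers 3 probes: center value = 0.3 / 3 = 0.1
        pos = np.array([0, 100, 200])
        out = smooth_differences(np.array([0.0, 0.3, 0.0]), pos,
                                 np.zeros(3, dtype=int), window_bp=100)
        assert out[1] == pytest.approx(0.1)
        assert out[0] == pytest.approx(0.15)  # edge window covers 2 probes

    def test_small_cluster_verbatim(self):
        pos = np.array([0, 100])
        d = np.array([0.3, -0.2])
        out = smooth_differences(d, pos, np.zeros(2, dtype=int), window_bp=1000)
        assert np.array_equal(out, d)

    @given(st.lists(st.floats(min_value=0.01, max_value=0.5), min_size=3, max_size=12))
    @settings(max_examples=50, derandomize=True)
    def test_constant_sign_preserved(self, diffs):
        d = np.asarray(diffs)
        pos = np.arange(len(d)) * 50
        out = smooth_differences(d, pos, np.zeros(len(d), dtype=int), window_bp=120)
        assert (out > 0).all()


class TestFindBumps:
    def test_hand_enumerated_region(self):
        sm = np.array([0.05, 0.15, 0.20, 0.12, 0.02])
        out = find_bumps(sm, np.zeros(5, dtype=int), cutoff=0.1)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r.start_idx, r.end_idx) == (1, 3)
        assert r.value == pytest.approx(0.47 / 3)
        assert r.area == pytest.approx(0.47)

    def test_subthreshold_yields_nothing(self):
        sm = np.full(6, 0.09)
        assert len(find_bumps(sm, np.zeros(6, dtype=int), cutoff=0.1)) == 0

    def test_sign_change_splits(self):
        sm = np.array([0.2, 0.2, -0.2, -0.2])
        out = find_bumps(sm, np.zeros(4, dtype=int), cutoff=0.1)
        assert len(out) == 2
        assert out["value"].iloc[0] > 0 > out["value"].iloc[1]

    def test_cluster_boundary_splits(self):
        sm = np.array([0.2, 0.2, 0.2])
        out = find_bumps(sm, np.array([0, 0, 1]), cutoff=0.1)
        assert len(out) == 2

    @given(st.lists(st.floats(min_value=-0.5, max_value=0.5), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_regions_respect_cutoff_and_direction(self, diffs):
        sm = np.asarray(diffs)
        out = find_bumps(sm, np.zeros(len(sm), dtype=int), cutoff=0.1)
        for r in out.itertuples(index=False):
            seg = sm[r.start_idx: r.end_idx + 1]
            assert (np.abs(seg) > 0.1).all()
            assert len(set(np.sign(seg))) == 1
            assert abs(r.value) > 0.1
            assert r.area == pytest.approx(np.abs(seg).sum())


class TestBH:
    def test_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_rank(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSummaries:
    def _dmr(self, i, value, context="island"):
        return DMRecord(region_id=f"r{i}", chrom="chr1", start=i * 100 + 1,
                        end=i * 100 + 50, probe_ids=("x",), value=value,
                        area=abs(value), context=context)

    def test_direction_share_bookkeeping(self):
        # 2,769 regions lower in group1 vs 261 higher: 91.4% hypomethylated in group1
        dmrs = [self._dmr(i, -0.2) for i in range(2769)] \
            + [self._dmr(3000 + i, 0.2) for i in range(261)]
        row = summarize_dmrs(dmrs).iloc[0]
        assert row.n_dmrs == 3030
        assert row.pct_hypo_group1 == pytest.approx(91.4)

    def test_empty_and_context_split(self):
        assert summarize_dmrs([]).iloc[0].n_dmrs == 0
        dmrs = [self._dmr(0, 0.2, "island"), self._dmr(1, 0.2, "island"),
                self._dmr(2, -0.2, "shore"), self._dmr(3, 0.2, "shore")]
        row = summarize_dmrs(dmrs).iloc[0]
        assert (row.pct_island, row.pct_shore, row.pct_shelf, row.pct_open_sea) \
            == (50.0, 50.0, 0.0, 0.0)


class TestCallerInvariance:
    def test_invariant_to_row_and_column_order(self, small_study, small_manifest,
                                               study_groups):
        beta, _, _, _ = small_study
        manifest, _, _ = small_manifest
        g1, g2 = study_groups
        res_a = BumpHunter(beta, manifest, g1, g2).fit(60, seed=9)
        rng = np.random.default_rng(3)
        beta_shuf = beta.iloc[rng.permutation(len(beta)),
                              rng.permutation(beta.shape[1])]
        man_shuf = manifest.iloc[rng.permutation(len(manifest))]
        res_b = BumpHunter(beta_shuf, man_shuf, g1, g2).fit(60, seed=9)
        pd.testing.assert_frame_equal(res_a.table, res_b.table)

    def test_pvalues_monotone_in_area(self, small_study, small_manifest, study_groups):
        beta, _, _, _ = small_study
        manifest, _, _ = small_manifest
        g1, g2 = study_groups
        t = BumpHunter(beta, manifest, g1, g2).fit(60, seed=4).table
        t = t.sort_values("area", ascending=False)
        assert (t["p_perm"].diff().dropna() >= -1e-12).all()
        assert (t["fwer"].diff().dropna() >= -1e-12).all()
        assert t["p_perm"].between(0, 1).all() and t["fwer"].between(0, 1).all()
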