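"""Profile classifier, LSC expression score, MDS and Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from lscsig import (DataError, DMRecord, ProfileClassifier, lsc_expression_score,
                    mds_top_variable, ward_cluster)
from lscsig.identity import linkage_to_newick, region_beta


def _panel(n_dmrs, probes_per=2):
    dmrs, rows = [], []
    for i in range(n_dmrs):
        probes = tuple(f"cg{i}_{j}" for j in range(probes_per))
        dmrs.append(DMRecord(region_id=f"d{i}", chrom="chr1",
                             start=i * 1000 + 1, end=i * 1000 + 500,
                             probe_ids=probes, value=-0.2, area=0.4))
        rows.extend(probes)
    return dmrs, rows


def _samples(ids, group):
    return pd.DataFrame({"sample_id": ids, "group": group})


class TestProfiles:
    def test_mean_and_unbiased_sd(self):
        dmrs, probes = _panel(1, probes_per=1)
        beta = pd.DataFrame({"a": [0.2], "b": [0.4]}, index=probes)
        clf = ProfileClassifier.from_reference(
            beta, _samples(["a", "b"], "HSC"), ["HSC"], dmrs)
        p = clf.profiles[0]
        assert p.mu[0] == pytest.approx(0.3)
        assert p.sd[0] == pytest.approx(0.14142, rel=1e-4)

    def test_sd_floor_applied(self):
        dmrs, probes = _panel(1, probes_per=1)
        beta = pd.DataFrame({"a": [0.3], "b": [0.3]}, index=probes)
        clf = ProfileClassifier.from_reference(
            beta, _samples(["a", "b"], "HSC"), ["HSC"], dmrs, sd_floor=0.01)
        assert clf.profiles[0].sd[0] == 0.01

    def test_sample_order_invariance_and_small_class_error(self):
        dmrs, probes = _panel(3)
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(rng.random((len(probes), 4)), index=probes,
                            columns=list("abcd"))
        samples = _samples(list("abcd"), "GMP")
        a = ProfileClassifier.from_reference(beta, samples, ["GMP"], dmrs)
        b = ProfileClassifier.from_reference(beta[list("dcba")], samples, ["GMP"], dmrs)
        assert np.allclose(a.profiles[0].mu, b.profiles[0].mu)
        with pytest.raises(DataError, match="need >= 2"):
            ProfileClassifier.from_reference(
                beta, _samples(list("abcd"), ["GMP", "GMP", "GMP", "MEP"]),
                ["MEP"], dmrs)


class TestScoring:
    def test_closed_form_at_profile_mean(self):
        dmrs, probes = _panel(2, probes_per=1)
        from lscsig.identity import ClassProfile
        prof = ClassProfile("A", tuple(d.region_id for d in dmrs),
                            mu=np.array([0.3, 0.6]), sd=np.array([1.0, 1.0]))
        clf = ProfileClassifier([prof])
        sc = clf.score_sample("s", np.array([0.3, 0.6]))
        assert sc.scores["A"] == pytest.approx(-np.log(2 * np.pi), abs=1e-10)

    def test_tie_broken_to_first_with_warning(self, caplog):
        from lscsig.identity import ClassProfile
        panel = ("d0",)
        p1 = ClassProfile("A", panel, np.array([0.5]), np.array([0.1]))
        p2 = ClassProfile("B", panel, np.array([0.5]), np.array([0.1]))
        clf = ProfileClassifier([p1, p2])
        with caplog.at_level("WARNING", logger="lscsig"):
            sc = clf.score_sample("s", np.array([0.4]))
        assert sc.assigned == "A" and sc.margin == 0.0
        assert any("tie" in r.message for r in caplog.records)

    def test_empty_cohort_and_missing_value_error(self):
        from lscsig.identity import ClassProfile
        prof = ClassProfile("A", ("d0",), np.array([0.5]), np.array([0.1]))
        clf = ProfileClassifier([prof])
        with pytest.raises(DataError, match="empty"):
            clf.assign(pd.DataFrame(index=["d0"]))
        with pytest.raises(DataError, match="missing"):
            clf.score_sample("s", np.array([np.nan]))


class TestLscScore:
    def test_single_gene_equals_centered_expression(self):
        expr = pd.DataFrame([[5.0, 6.0, 7.0, 8.0]], index=["G1", ],
                            columns=list("abcd"))
        # PC1 of 1-D data is the centred value itself
        expr2 = pd.concat([expr, expr])  # need >= 2 genes; duplicate row
        expr2.index = ["G1", "G2"]
        out = lsc_expression_score(expr2, ["G1", "G2"])
        centered = expr.iloc[0] - expr.iloc[0].mean()
        assert np.allclose(out["score"], centered * np.sqrt(2))
        assert list(out["stratum"]) == ["low", "low", "high", "high"]

    def test_two_correlated_genes_common_factor(self):
        rng = np.random.default_rng(1)
        f = rng.normal(0, 1, 30)
        expr = pd.DataFrame([6 + f, 8 + f], index=["G1", "G2"],
                            columns=[f"s{i}" for i in range(30)])
        out = lsc_expression_score(expr, ["G1", "G2"], up_genes=["G1", "G2"])
        # eigenvector (1,1)/sqrt(2): score proportional to the common factor
        r = np.corrcoef(out["score"], f)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_median_split_sizes(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(7, 1, (5, 182)),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(182)])
        out = lsc_expression_score(expr, [f"G{i}" for i in range(5)])
        counts = out["stratum"].value_counts()
        assert counts["high"] == 91 and counts["low"] == 91

    def test_gene_order_invariance_and_orientation(self):
        rng = np.random.default_rng(3)
        f = rng.normal(0, 1, 40)
        up = pd.DataFrame([7 + f + rng.normal(0, .2, 40) for _ in range(4)],
                          index=[f"U{i}" for i in range(4)])
        down = pd.DataFrame([7 - f + rng.normal(0, .2, 40) for _ in range(3)],
                            index=[f"D{i}" for i in range(3)])
        expr = pd.concat([up, down])
        expr.columns = [f"s{i}" for i in range(40)]
        genes = list(expr.index)
        a = lsc_expression_score(expr, genes, up_genes=[f"U{i}" for i in range(4)])
        b = lsc_expression_score(expr, genes[::-1], up_genes=[f"U{i}" for i in range(4)])
        assert np.allclose(a["score"], b["score"])
        # orientation: high stratum is the one enriched for up-gene expression
        hi = a.loc[a.stratum == "high", "sample_id"]
        lo = a.loc[a.stratum == "low", "sample_id"]
        up_expr = expr.loc[[f"U{i}" for i in range(4)]]
        assert up_expr[hi].to_numpy().mean() > up_expr[lo].to_numpy().mean()

    def test_constant_expression_errors(self):
        expr = pd.DataFrame(np.full((3, 6), 5.0), index=["G1", "G2", "G3"],
                            columns=list("abcdef"))
        with pytest.raises(DataError, match="PC1"):
            lsc_expression_score(expr, ["G1", "G2", "G3"])


class TestMDS:
    def test_distance_preservation_3_4_5(self):
        # three samples with pairwise Euclidean distances 3, 4, 5
        n = 25
        X = np.zeros((n, 3))
        X[:9, 1] = 1.0    # d(a,b) = 3
        X[9:, 2] = 1.0    # d(a,c) = 4, d(b,c) = 5
        beta = pd.DataFrame(X, index=[f"cg{i}" for i in range(n)],
                            columns=["a", "b", "c"])
        coords = mds_top_variable(beta, k=n)
        d = pdist(coords.to_numpy())
        assert np.allclose(np.sort(d), [3, 4, 5], atol=1e-9)
        assert np.allclose(coords.mean(axis=0), 0, atol=1e-9)

    def test_identical_samples_coincide_and_k_checked(self):
        rng = np.random.default_rng(4)
        v = rng.random(30)
        beta = pd.DataFrame({"a": v, "b": v, "c": rng.random(30)},
                            index=[f"cg{i}" for i in range(30)])
        coords = mds_top_variable(beta, k=10)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-6)
        with pytest.raises(DataError, match="exceeds"):
            mds_top_variable(beta, k=31)

    def test_snp_probes_excluded(self):
        rng = np.random.default_rng(5)
        beta = pd.DataFrame(rng.random((20, 4)),
                            index=[f"cg{i}" for i in range(20)],
                            columns=list("abcd"))
        flags = pd.Series(True, index=beta.index[:15])
        with pytest.raises(DataError, match="exceeds"):
            mds_top_variable(beta, k=10, snp_flags=flags)


class TestWard:
    def test_duplicate_sample_merges_first(self):
        rng = np.random.default_rng(6)
        reg = pd.DataFrame(rng.random((10, 3)), columns=["a", "b", "c"])
        reg["d"] = reg["a"]
        Z, labels = ward_cluster(reg, 2)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.3, 0.5, 12)
        cols = {}
        for i in range(6):
            cols[f"x{i}"] = np.clip(base + rng.normal(0, 0.02, 12), 0, 1)
        for i in range(6):
            cols[f"y{i}"] = np.clip(base + 0.3 + rng.normal(0, 0.02, 12), 0, 1)
        reg = pd.DataFrame(cols)
        _, labels = ward_cluster(reg, 2)
        assert labels[[f"x{i}" for i in range(6)]].nunique() == 1
        assert labels[[f"y{i}" for i in range(6)]].nunique() == 1
        assert labels["x0"] != labels["y0"]

    def test_newick_roundtrip_leaf_count(self):
        rng = np.random.default_rng(8)
        reg = pd.DataFrame(rng.random((5, 4)), columns=list("abcd"))
        Z, _ = ward_cluster(reg, 2)
        nwk = linkage_to_newick(Z, list("abcd"))
        assert nwk.endswith(";") and all(c in nwk for c in "abcd")


class TestRegionBeta:
    def test_unweighted_probe_mean(self):
        dmrs, probes = _panel(1, probes_per=3)
        beta = pd.DataFrame({"s1": [0.1, 0.2, 0.6]}, index=probes)
        reg = region_beta(beta, dmrs)
        assert reg.loc["d0", "s1"] == pytest.approx(0.3)
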