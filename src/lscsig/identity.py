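"""Cell-identity assignment from reference methylation profiles.

Each reference class (LSC/Blast, or the six normal haematopoietic
stem/progenitor populations HSC, MPP, L-MPP, CMP, GMP, MEP) is summarized
per DMR by the mean and standard deviation (n-1 denominator, floored) of its
region-level beta values across the class's reference samples.  A query
sample's score for class c is the summed Gaussian log density

    score(c) = sum_d [ -1/2 log(2 pi sd_dc^2) - (x_d - mu_dc)^2 / (2 sd_dc^2) ]

over the DMR panel; the class with maximal score is assigned (deterministic
tie-break by profile order, with a warning).

Also here: the LSC expression score (first principal component of signature-
gene expression, median-split into high/low), classical multidimensional
scaling of the top-variance probes, and Ward hierarchical clustering on
region-level beta values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import DataError, DMRecord

log = logging.getLogger("lscsig")


def region_beta(beta: pd.DataFrame, dmrs: list[DMRecord]) -> pd.DataFrame:
    """Regions x samples matrix: unweighted mean beta over member probes."""
    rows = {}
    for d in dmrs:
        missing = [p for p in d.probe_ids if p not in beta.index]
        if missing:
            raise DataError(f"{d.region_id}: probes absent from beta matrix: {missing[:5]}")
        rows[d.region_id] = beta.loc[list(d.probe_ids)].mean(axis=0)
    return pd.DataFrame(rows).T


@dataclass
class ClassProfile:
    """Per-DMR (mean, sd) methylation profile of one reference class."""

    class_name: str
    dmr_ids: tuple[str, ...]
    mu: np.ndarray
    sd: np.ndarray


@dataclass
class IdentityScore:
    sample_id: str
    scores: dict[str, float]
    assigned: str
    margin: float


class ProfileClassifier:
    """Gaussian log-density classifier over a DMR panel.

    Build with :meth:`from_reference` (fits one :class:`ClassProfile` per
    reference class), then :meth:`score_sample` / :meth:`assign` for queries.
    """

    def __init__(self, profiles: list[ClassProfile]):
        if not profiles:
            raise DataError("no class profiles")
        panel = profiles[0].dmr_ids
        for p in profiles:
            if p.dmr_ids != panel:
                raise DataError("profiles disagree on the DMR panel")
        self.profiles = profiles
        self.dmr_ids = panel

    @classmethod
    def from_reference(cls, beta: pd.DataFrame, samples: pd.DataFrame,
                       classes: list[str], dmrs: list[DMRecord], *,
                       sd_floor: float = 0.01) -> "ProfileClassifier":
        """Fit per-class (mean, sd) profiles from reference samples.

        ``samples`` maps sample_id -> group; each class needs >= 2 reference
        samples (sd undefined otherwise).  sd uses the n-1 denominator and is
        floored at ``sd_floor``.
        """
        if sd_floor <= 0:
            raise DataError("sd_floor must be > 0")
        reg = region_beta(beta, dmrs)
        groups = samples.set_index("sample_id")["group"]
        profiles = []
        for cname in classes:
            ids = [s for s in reg.columns if groups.get(s) == cname]
            if len(ids) < 2:
                raise DataError(f"class {cname!r} has {len(ids)} reference "
                                "samples; need >= 2")
            sub = reg[ids].to_numpy()
            mu = sub.mean(axis=1)
            sd = np.maximum(sub.std(axis=1, ddof=1), sd_floor)
            profiles.append(ClassProfile(cname, tuple(reg.index), mu, sd))
        return cls(profiles)

    def score_sample(self, sample_id: str, x: np.ndarray) -> IdentityScore:
        """Summed Gaussian log-density score per class; argmax assignment."""
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.dmr_ids),):
            raise DataError(f"sample vector length {x.shape} != panel size "
                            f"{len(self.dmr_ids)}")
        if not np.isfinite(x).all():
            raise DataError(f"{sample_id}: missing DMR-level beta values")
        scores = {}
        for p in self.profiles:
            z = (x - p.mu) / p.sd
            scores[p.class_name] = float(
                -0.5 * np.sum(np.log(2 * np.pi * p.sd ** 2)) - 0.5 * np.sum(z ** 2))
        vals = list(scores.values())
        best = max(vals)
        winners = [c for c, v in scores.items() if v == best]
        if len(winners) > 1:
            log.warning("identity: tie between %s for %s; keeping first",
                        winners, sample_id)
        assigned = winners[0]
        second = max((v for c, v in scores.items() if c != assigned), default=best)
        return IdentityScore(sample_id, scores, assigned, best - second)

    def assign(self, cohort_region_beta: pd.DataFrame) -> pd.DataFrame:
        """Assign every cohort sample (columns) over the region x sample matrix."""
        if cohort_region_beta.shape[1] == 0:
            raise DataError("empty cohort")
        aligned = cohort_region_beta.loc[list(self.dmr_ids)]
        rows = []
        for s in aligned.columns:
            sc = self.score_sample(s, aligned[s].to_numpy())
            row = {"sample_id": s, "assigned": sc.assigned, "margin": sc.margin}
            row.update({f"score_{c}": v for c, v in sc.scores.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def composition(self, assignments: pd.DataFrame) -> pd.Series:
        """Fraction of cohort samples assigned to each class (sums to 1)."""
        frac = assignments["assigned"].value_counts(normalize=True)
        return frac.reindex([p.class_name for p in self.profiles], fill_value=0.0)


def assign_cohort(cohort_beta: pd.DataFrame, classifier: ProfileClassifier,
                  dmrs: list[DMRecord]) -> tuple[pd.DataFrame, pd.Series]:
    """Assign a probe-level cohort beta matrix; returns (assignments, composition)."""
    reg = region_beta(cohort_beta, dmrs)
    assignments = classifier.assign(reg)
    return assignments, classifier.composition(assignments)


# ---------------------------------------------------------------------------
# LSC expression score


def lsc_expression_score(expr: pd.DataFrame, signature_genes: list[str],
                         up_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-sample LSC score: PC1 of signature-gene expression, median split.

    Genes are centred before the decomposition.  The PC1 sign is fixed so
    the score correlates positively with the mean expression of the LSC-up
    genes (``up_genes``; defaults to all signature genes).  Samples above the
    median are 'high', ties go to 'low'; the strata differ in size by <= 1.
    """
    present = [g for g in signature_genes if g in expr.index]
    if len(present) < 2:
        raise DataError(f"need >= 2 signature genes in the expression matrix, "
                        f"found {len(present)}")
    if len(present) < len(signature_genes):
        log.warning("lsc score: %d/%d signature genes absent from expression",
                    len(signature_genes) - len(present), len(signature_genes))
    X = expr.loc[present].to_numpy(dtype=float)          # genes x samples
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0):
        raise DataError("all-constant expression; PC1 undefined")
    # PC1 sample coordinates via SVD of the gene-centred matrix
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    score = s[0] * vt[0]
    up = [g for g in (up_genes if up_genes is not None else present) if g in present]
    ref = expr.loc[up].mean(axis=0).to_numpy() if up else score
    if np.corrcoef(score, ref)[0, 1] < 0:
        score = -score
    med = np.median(score)
    stratum = np.where(score > med, "high", "low")
    return pd.DataFrame({"sample_id": expr.columns, "score": score,
                         "stratum": stratum})


# ---------------------------------------------------------------------------
# ordination and clustering


def mds_top_variable(beta: pd.DataFrame, k: int = 1000,
                     snp_flags: pd.Series | None = None) -> pd.DataFrame:
    """Classical MDS (principal coordinates) on the top-k most variable probes.

    SNP-overlapping probes (``snp_flags`` indexed by probe id) are removed
    before ranking by variance.  Classical scaling of Euclidean distances is
    computed by double-centred eigendecomposition (cmdscale-equivalent);
    coordinates are centred at zero.
    """
    sub = beta
    if snp_flags is not None:
        keep = [p for p in beta.index if not bool(snp_flags.get(p, False))]
        sub = beta.loc[keep]
    if k > len(sub):
        raise DataError(f"k={k} exceeds {len(sub)} available probes")
    variances = sub.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False).index[:k]
    X = sub.loc[top].to_numpy(dtype=float).T            # samples x probes
    # double-centred squared-distance matrix
    d2 = np.square(np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2))
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1]
    coords = v[:, order[:2]] * np.sqrt(np.maximum(w[order[:2]], 0.0))
    return pd.DataFrame(coords, index=beta.columns, columns=["mds1", "mds2"])


def ward_cluster(region_beta_matrix: pd.DataFrame, n_clusters: int
                 ) -> tuple[np.ndarray, pd.Series]:
    """Ward hierarchical clustering of samples on region-level beta values.

    Returns the scipy linkage matrix and flat labels from cutting the tree
    at ``n_clusters``.  Deterministic given input order.
    """
    if region_beta_matrix.shape[1] < 2:
        raise DataError("need >= 2 samples to cluster")
    X = region_beta_matrix.to_numpy(dtype=float).T      # samples x regions
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, pd.Series(labels, index=region_beta_matrix.columns, name="cluster")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
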