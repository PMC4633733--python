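"""Bump-hunting detection of differentially methylated regions (DMRs).

Two groups of samples are compared probe-by-probe on beta values; per-probe
mean differences are smoothed within probe clusters (consecutive probes no
further apart than ``maxgap``); maximal runs of smoothed differences beyond a
cutoff (default 0.1, i.e. 10% methylation difference) become candidate
regions scored by their area (sum of absolute smoothed differences).
Significance comes from permutation of the pooled sample labels with group
sizes preserved: the whole pipeline is re-run per permutation and region
areas are referred to the pooled null (p_perm) and to the per-permutation
maximum null area (family-wise error rate).

The model object is :class:`BumpHunter`; its :meth:`BumpHunter.fit` returns a
:class:`DMRResults` carrying the called regions, their p-values and the
direction/context summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import DataError, DMRecord, dmr_frame

log = logging.getLogger("lscsig")


# ---------------------------------------------------------------------------
# elementary operations (each independently testable)


def probe_group_difference(beta: pd.DataFrame, samples1, samples2) -> pd.Series:
    """Per-probe mean beta difference, group1 - group2.

    Groups must be disjoint with >= 2 samples each; a sample id absent from
    the matrix is a hard error.
    """
    samples1, samples2 = list(samples1), list(samples2)
    if len(samples1) < 2 or len(samples2) < 2:
        raise DataError("each group needs >= 2 samples")
    if set(samples1) & set(samples2):
        raise DataError("groups overlap")
    missing = (set(samples1) | set(samples2)) - set(beta.columns)
    if missing:
        raise DataError(f"sample ids missing from beta matrix: {sorted(missing)}")
    return beta[samples1].mean(axis=1) - beta[samples2].mean(axis=1)


def cluster_probes(manifest: pd.DataFrame, maxgap: int) -> np.ndarray:
    """Cluster ids for probes sorted by (chrom, pos).

    Consecutive probes on the same chromosome with gap <= maxgap share a
    cluster; clusters never span chromosomes.  ``manifest`` must already be
    sorted by (chrom, pos).
    """
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    n = len(manifest)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    new = np.ones(n, dtype=bool)
    new[1:] = (chrom[1:] != chrom[:-1]) | ((pos[1:] - pos[:-1]) > maxgap)
    return np.cumsum(new) - 1


def _window_bounds(pos: np.ndarray, chrom_codes: np.ndarray, clusters: np.ndarray,
                   window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive index bounds [lo, hi] of each probe's smoothing window.

    The window spans probes within +/- window_bp on the same chromosome,
    clipped to the probe's cluster; clusters with < 3 probes smooth over the
    probe alone (returned verbatim).
    """
    n = len(pos)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    # chromosome blocks are contiguous in sorted order
    for code in np.unique(chrom_codes):
        blk = np.flatnonzero(chrom_codes == code)
        b0, b1 = blk[0], blk[-1] + 1
        p = pos[b0:b1]
        lo[b0:b1] = b0 + np.searchsorted(p, p - window_bp, side="left")
        hi[b0:b1] = b0 + np.searchsorted(p, p + window_bp, side="right") - 1
    # clip to cluster bounds
    cstart = np.zeros(n, dtype=np.int64)
    first = np.ones(n, dtype=bool)
    first[1:] = clusters[1:] != clusters[:-1]
    starts = np.flatnonzero(first)
    ends = np.append(starts[1:] - 1, n - 1)
    sizes = ends - starts + 1
    cl_start = starts[clusters]
    cl_end = ends[clusters]
    lo = np.maximum(lo, cl_start)
    hi = np.minimum(hi, cl_end)
    small = sizes[clusters] < 3
    idx = np.arange(n)
    lo[small] = idx[small]
    hi[small] = idx[small]
    return lo, hi


def smooth_differences(diffs: np.ndarray, positions: np.ndarray,
                       clusters: np.ndarray, window_bp: int,
                       chrom_codes: np.ndarray | None = None) -> np.ndarray:
    """Running mean of per-probe differences within +/- window_bp.

    Probes in clusters of fewer than 3 members are returned unsmoothed.
    The running mean of a constant-sign cluster never changes sign.
    """
    diffs = np.asarray(diffs, dtype=float)
    if chrom_codes is None:
        chrom_codes = np.zeros(len(diffs), dtype=np.int64)
    lo, hi = _window_bounds(np.asarray(positions), chrom_codes, clusters, window_bp)
    return _smooth_with_bounds(diffs, lo, hi)


def _smooth_with_bounds(diffs: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    cs = np.concatenate(([0.0], np.cumsum(diffs)))
    return (cs[hi + 1] - cs[lo]) / (hi + 1 - lo)


def _bump_runs(smoothed: np.ndarray, clusters: np.ndarray, cutoff: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (inclusive) indices of maximal same-sign supra-cutoff runs."""
    state = np.zeros(len(smoothed), dtype=np.int8)
    state[smoothed > cutoff] = 1
    state[smoothed < -cutoff] = -1
    n = len(state)
    if n == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    new = np.ones(n, dtype=bool)
    new[1:] = (state[1:] != state[:-1]) | (clusters[1:] != clusters[:-1])
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:] - 1, n - 1)
    keep = state[starts] != 0
    return starts[keep], ends[keep]


def find_bumps(smoothed: np.ndarray, clusters: np.ndarray, cutoff: float,
               min_probes: int = 1) -> pd.DataFrame:
    """Candidate regions: maximal runs beyond +/- cutoff within a cluster.

    Returns a frame with start/end probe indices (inclusive), number of
    probes, mean smoothed difference (``value``) and area (sum |smoothed|).
    A sign change inside a run splits the region.
    """
    if cutoff <= 0:
        raise DataError("cutoff must be > 0")
    smoothed = np.asarray(smoothed, dtype=float)
    starts, ends = _bump_runs(smoothed, np.asarray(clusters), cutoff)
    npb = ends - starts + 1
    keep = npb >= min_probes
    starts, ends, npb = starts[keep], ends[keep], npb[keep]
    cs = np.concatenate(([0.0], np.cumsum(smoothed)))
    sums = cs[ends + 1] - cs[starts]
    return pd.DataFrame({
        "start_idx": starts,
        "end_idx": ends,
        "n_probes": npb,
        "value": sums / npb,
        "area": np.abs(sums),  # constant sign within a run
    })


def _null_areas(smoothed: np.ndarray, clusters: np.ndarray, cutoff: float,
                min_probes: int) -> np.ndarray:
    starts, ends = _bump_runs(smoothed, clusters, cutoff)
    npb = ends - starts + 1
    keep = npb >= min_probes
    starts, ends = starts[keep], ends[keep]
    cs = np.concatenate(([0.0], np.cumsum(smoothed)))
    return np.abs(cs[ends + 1] - cs[starts])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_dmrs(dmrs) -> pd.DataFrame:
    """Direction counts and context percentage summary (one row).

    Percentages by CpG context sum to 100 up to rounding; ``pct_hypo_group1``
    is the share of regions where group1 is the hypomethylated one
    (group2 > group1).
    """
    table = dmr_frame(list(dmrs))
    n = len(table)
    row: dict = {"n_dmrs": n}
    n_g1 = int((table["value"] > 0).sum()) if n else 0
    n_g2 = n - n_g1
    row["n_group1_gt"] = n_g1
    row["n_group2_gt"] = n_g2
    row["pct_hypo_group1"] = round(100.0 * n_g2 / n, 1) if n else 0.0
    row["pct_hypo_group2"] = round(100.0 * n_g1 / n, 1) if n else 0.0
    for ctx in ("island", "shore", "shelf", "open_sea"):
        row[f"pct_{ctx}"] = round(100.0 * (table["context"] == ctx).sum() / n, 1) if n else 0.0
    return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# model / results


@dataclass
class DMRResults:
    """Fitted DMR call set with permutation p-values.

    ``dmrs`` holds one :class:`~lscsig.io.DMRecord` per region, sorted by
    decreasing area; ``table`` the same as a DataFrame.  ``null_areas`` and
    ``perm_max_areas`` expose the permutation null for diagnostics.
    """

    dmrs: list[DMRecord]
    group1: list[str]
    group2: list[str]
    n_permutations: int
    exhaustive: bool
    null_areas: np.ndarray = field(repr=False)
    perm_max_areas: np.ndarray = field(repr=False)
    params: dict = field(default_factory=dict)

    @property
    def table(self) -> pd.DataFrame:
        return dmr_frame(self.dmrs)

    def significant(self, p_cutoff: float = 0.01) -> list[DMRecord]:
        return [d for d in self.dmrs if d.p_perm < p_cutoff]

    def summary(self) -> str:
        t = self.table
        head = (
            f"BumpHunter results: {len(self.dmrs)} candidate regions, "
            f"{len(self.group1)} vs {len(self.group2)} samples, "
            f"{self.n_permutations} permutations"
            f"{' (exhaustive)' if self.exhaustive else ''}\n"
            f"params: {self.params}\n"
        )
        if len(t) == 0:
            return head + "(no regions)"
        return head + t.head(20).to_string(index=False)


class BumpHunter:
    """Two-group bump-hunting DMR model on a beta matrix.

    Parameters
    ----------
    beta : DataFrame
        probes x samples beta values.
    manifest : DataFrame
        probe manifest with probe_id/chrom/pos (and optionally context);
        defines probe order and clustering.
    group1, group2 : sequences of sample ids
        the two disjoint comparison groups (>= 2 samples each).
    cutoff : float
        minimum |smoothed difference| (beta units) for a candidate region.
    maxgap : int
        bp gap above which consecutive probes start a new cluster.
    smooth_window : int
        bp half-window of the running-mean smoother.
    """

    def __init__(self, beta: pd.DataFrame, manifest: pd.DataFrame, group1, group2, *,
                 cutoff: float = 0.1, maxgap: int = 500, smooth_window: int = 1000,
                 min_probes: int = 1):
        if cutoff <= 0:
            raise DataError("cutoff must be > 0")
        self.group1, self.group2 = list(group1), list(group2)
        # validation of groups happens here via probe_group_difference's checks
        probe_group_difference(beta, self.group1, self.group2)
        order = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        missing = set(order["probe_id"]) - set(beta.index)
        if missing:
            raise DataError(f"manifest probes absent from beta matrix: {sorted(missing)[:5]}")
        self.manifest = order
        pooled = self.group1 + self.group2
        self._values = beta.loc[order["probe_id"], pooled].to_numpy(dtype=float)
        self._pos = order["pos"].to_numpy()
        self._chrom = order["chrom"].to_numpy()
        self._chrom_codes = pd.factorize(order["chrom"])[0]
        self.cutoff = float(cutoff)
        self.maxgap = int(maxgap)
        self.smooth_window = int(smooth_window)
        self.min_probes = int(min_probes)
        self.clusters = cluster_probes(order, self.maxgap)
        self._lo, self._hi = _window_bounds(self._pos, self._chrom_codes,
                                            self.clusters, self.smooth_window)
        self._n1, self._n2 = len(self.group1), len(self.group2)

    # -- internal pipeline on an arbitrary group1 index set ------------------
    def _smoothed_for(self, idx1: np.ndarray) -> np.ndarray:
        n = self._n1 + self._n2
        w = np.full(n, -1.0 / self._n2)
        w[idx1] = 1.0 / self._n1
        return _smooth_with_bounds(self._values @ w, self._lo, self._hi)

    def observed_candidates(self) -> pd.DataFrame:
        sm = self._smoothed_for(np.arange(self._n1))
        return find_bumps(sm, self.clusters, self.cutoff, self.min_probes)

    def fit(self, n_permutations: int = 250, seed: int | None = None) -> DMRResults:
        """Call candidate regions and assign permutation p-values and FWER.

        Labels are permuted over the pooled samples with group sizes
        preserved, the full pipeline re-run per permutation.  When fewer
        distinct label assignments than ``n_permutations`` exist the null is
        enumerated exhaustively instead (noted in the log).
        p_perm(r) = (1 + #{null regions with area >= area(r)})
                    / (1 + total null regions);
        fwer(r)  = (1 + #{permutations with max null area >= area(r)})
                    / (1 + B).
        """
        if n_permutations < 1:
            raise DataError("n_permutations must be >= 1")
        cand = self.observed_candidates()
        n = self._n1 + self._n2
        n_distinct = math.comb(n, self._n1)
        exhaustive = n_distinct <= n_permutations
        if exhaustive:
            assignments = [np.array(c) for c in
                           itertools.combinations(range(n), self._n1)]
            log.info("exhaustive permutation null: %d label assignments "
                     "(requested %d)", n_distinct, n_permutations)
        else:
            rng = np.random.default_rng(seed)
            assignments = [rng.permutation(n)[: self._n1]
                           for _ in range(n_permutations)]
        null_chunks = []
        perm_max = np.zeros(len(assignments))
        for b, idx1 in enumerate(assignments):
            areas = _null_areas(self._smoothed_for(idx1), self.clusters,
                                self.cutoff, self.min_probes)
            null_chunks.append(areas)
            perm_max[b] = areas.max() if areas.size else 0.0
        null_areas = (np.concatenate(null_chunks) if null_chunks
                      else np.empty(0))
        null_sorted = np.sort(null_areas)
        max_sorted = np.sort(perm_max)
        B = len(assignments)

        area = cand["area"].to_numpy()
        n_ge_null = len(null_sorted) - np.searchsorted(null_sorted, area, side="left")
        p_perm = (1.0 + n_ge_null) / (1.0 + len(null_sorted))
        n_ge_max = B - np.searchsorted(max_sorted, area, side="left")
        fwer = (1.0 + n_ge_max) / (1.0 + B)
        p_bh = bh_adjust(p_perm) if len(p_perm) else p_perm

        probe_ids = self.manifest["probe_id"].to_numpy()
        contexts = (self.manifest["context"].to_numpy()
                    if "context" in self.manifest.columns else None)
        records = []
        order = np.argsort(-area, kind="mergesort")
        for rank, i in enumerate(order):
            s, e = int(cand["start_idx"].iloc[i]), int(cand["end_idx"].iloc[i])
            members = tuple(probe_ids[s:e + 1])
            ctx = ""
            if contexts is not None:
                vals, counts = np.unique(contexts[s:e + 1], return_counts=True)
                ctx = str(vals[np.argmax(counts)])
            records.append(DMRecord(
                region_id=f"dmr_{rank + 1:05d}",
                chrom=str(self._chrom[s]),
                start=int(self._pos[s]),
                end=int(self._pos[e]),
                probe_ids=members,
                value=float(cand["value"].iloc[i]),
                area=float(cand["area"].iloc[i]),
                p_perm=float(p_perm[i]),
                fwer=float(fwer[i]),
                p_bh=float(p_bh[i]),
                context=ctx,
            ))
        return DMRResults(
            dmrs=records,
            group1=self.group1,
            group2=self.group2,
            n_permutations=B,
            exhaustive=exhaustive,
            null_areas=null_areas,
            perm_max_areas=perm_max,
            params={"cutoff": self.cutoff, "maxgap": self.maxgap,
                    "smooth_window": self.smooth_window,
                    "min_probes": self.min_probes},
        )
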