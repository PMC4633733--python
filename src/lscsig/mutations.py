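"""Mutation association of signature DMRs.

For each recurrent AML mutation, a wild-type-vs-mutant DMR comparison yields
a mutation-specific region set.  Every signature DMR is then classed as
upstream-regulator-associated (NPM1/ASXL1-type), epigenome-modifying-
enzyme-associated (DNMT3A/IDH/TET-type), both, or mutation independent,
by region overlap (default: at least one shared probe).  A chi-square
enrichment test on a 2x2 overlap table against a non-overlapping array
background supports sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import BumpHunter, DMRResults
from .io import DataError, DMRecord
from .signature import SignatureEntry

log = logging.getLogger("lscsig")

P_FLOOR = 2.2e-16  # machine-reportable floor, reported as "< 2.2e-16"


@dataclass
class MutationDMRSets:
    """DMRs from one wild-type vs mutant comparison."""

    gene: str
    dmrs: list[DMRecord]
    n_mutant: int
    n_wildtype: int
    results: DMRResults | None = None


def mutation_dmrs(beta: pd.DataFrame, samples: pd.DataFrame, mutation_gene: str, *,
                  manifest: pd.DataFrame, p_cutoff: float = 0.01,
                  n_permutations: int = 250, seed: int | None = None,
                  **caller_params) -> MutationDMRSets:
    """DMR analysis between mutant (group1) and wild-type (group2) samples.

    Raises if the genotype column is absent or either group has < 2 samples
    (e.g. a mutation with no carriers in the cohort).
    """
    col = f"mut_{mutation_gene}"
    if col not in samples.columns:
        raise DataError(f"no genotype column for mutation {mutation_gene!r}")
    geno = samples.set_index("sample_id")[col]
    geno = geno[geno.index.isin(beta.columns)].dropna()
    mutant = geno.index[geno == 1].tolist()
    wildtype = geno.index[geno == 0].tolist()
    if len(mutant) < 2 or len(wildtype) < 2:
        raise DataError(
            f"mutation {mutation_gene!r}: {len(mutant)} mutant / "
            f"{len(wildtype)} wild-type samples; need >= 2 in each group")
    model = BumpHunter(beta, manifest, mutant, wildtype, **caller_params)
    res = model.fit(n_permutations=n_permutations, seed=seed)
    return MutationDMRSets(gene=mutation_gene,
                           dmrs=res.significant(p_cutoff),
                           n_mutant=len(mutant), n_wildtype=len(wildtype),
                           results=res)


# ---------------------------------------------------------------------------
# overlap and classification


def _regions_overlap(a: DMRecord, b: DMRecord, rule: str) -> bool:
    if rule == "probe":
        return bool(set(a.probe_ids) & set(b.probe_ids))
    if rule == "bp":
        return a.chrom == b.chrom and a.start <= b.end and a.end >= b.start
    raise DataError(f"unknown overlap rule {rule!r}")


def _overlaps_any(region: DMRecord, dmr_sets, rule: str) -> bool:
    return any(_regions_overlap(region, d, rule)
               for s in dmr_sets for d in s.dmrs)


def classify_signature(signature: list[SignatureEntry],
                       upstream_sets: list[MutationDMRSets],
                       enzyme_sets: list[MutationDMRSets], *,
                       overlap_rule: str = "probe") -> pd.Series:
    """Fill each entry's mutation_class in place; return category counts.

    upstream if the signature DMR overlaps any upstream-regulator mutation
    set only; enzyme if any enzyme set only; both if at least one of each;
    independent otherwise.  The four counts partition the signature.
    """
    counts = {"upstream": 0, "enzyme": 0, "both": 0, "independent": 0}
    for entry in signature:
        up = _overlaps_any(entry.region, upstream_sets, overlap_rule)
        enz = _overlaps_any(entry.region, enzyme_sets, overlap_rule)
        if up and enz:
            cls = "both"
        elif up:
            cls = "upstream"
        elif enz:
            cls = "enzyme"
        else:
            cls = "independent"
        entry.mutation_class = cls
        counts[cls] += 1
    return pd.Series(counts)


# ---------------------------------------------------------------------------
# enrichment


def dmr_set_enrichment(set_a: list[DMRecord], set_b: list[DMRecord],
                       background_regions: list[DMRecord], *,
                       overlap_rule: str = "probe") -> dict:
    """Chi-square (df=1) enrichment of overlap between two DMR sets.

    2x2 table: [overlap a&b, a-only] vs [b-only, background-only]; Pearson
    chi-square without continuity correction, one-sided upper-tail p.
    The background must not overlap either set.  p below 2.2e-16 is flagged
    with the conventional "< 2.2e-16" string alongside the numeric value.
    """
    for bg in background_regions:
        if _overlaps_any(bg, [MutationDMRSets("a", set_a, 2, 2),
                              MutationDMRSets("b", set_b, 2, 2)], overlap_rule):
            raise DataError("background region overlaps a tested set")
    in_b = [_overlaps_any(a, [MutationDMRSets("b", set_b, 2, 2)], overlap_rule)
            for a in set_a]
    n_overlap = int(sum(in_b))
    n_a_only = len(set_a) - n_overlap
    n_b_only = len(set_b) - n_overlap
    if n_b_only < 0:
        raise DataError("set_b smaller than its overlap with set_a")
    n_bg = len(background_regions)
    table = np.array([[n_overlap, n_a_only], [n_b_only, n_bg]], dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    if (expected < 1).any():
        log.warning("enrichment: expected cell count below 1 (table %s)",
                    table.tolist())
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "table": table.astype(int).tolist(),
        "chi2": chi2,
        "df": 1,
        "p": p,
        "p_report": "< 2.2e-16" if p < P_FLOOR else f"{p:.3g}",
    }


def length_matched_random_regions(dmrs: list[DMRecord], manifest: pd.DataFrame,
                                  seed: int | None = None) -> list[DMRecord]:
    """Random control regions with the same per-region probe-count multiset.

    Regions are runs of consecutive manifest probes drawn from probes not in
    any input DMR; output regions are mutually disjoint and never overlap the
    input set.  Raises if matching is infeasible.
    """
    rng = np.random.default_rng(seed)
    order = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    used = set().union(*(set(d.probe_ids) for d in dmrs)) if dmrs else set()
    free = ~order["probe_id"].isin(used).to_numpy()
    probe_ids = order["probe_id"].to_numpy()
    chrom = order["chrom"].to_numpy()
    pos = order["pos"].to_numpy()
    sizes = sorted((d.n_probes for d in dmrs), reverse=True)
    # candidate start positions of free runs, rebuilt after each draw
    taken = np.zeros(len(order), dtype=bool)
    out: list[DMRecord] = []
    for k, size in enumerate(sizes):
        ok = free & ~taken
        # run of `size` consecutive probes, all free, same chromosome
        valid = np.ones(len(order) - size + 1, dtype=bool)
        for off in range(size):
            valid &= ok[off: len(order) - size + 1 + off]
        valid &= chrom[: len(order) - size + 1] == chrom[size - 1:]
        starts = np.flatnonzero(valid)
        if starts.size == 0:
            raise DataError(
                f"cannot place region of {size} probes: background exhausted "
                f"({len(sizes) - k} regions still to place)")
        s = int(rng.choice(starts))
        taken[s: s + size] = True
        out.append(DMRecord(
            region_id=f"rand_{k + 1:05d}",
            chrom=str(chrom[s]),
            start=int(pos[s]),
            end=int(pos[s + size - 1]),
            probe_ids=tuple(probe_ids[s: s + size]),
            value=0.0,
            area=0.0,
        ))
    return out
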