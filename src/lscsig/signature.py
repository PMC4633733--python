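"""Integration of DMRs with expression into the LSC epigenetic signature.

A DMR enters the signature when (i) its permutation p is below the cutoff,
(ii) it overlaps a gene's promoter window (+/- 2 kb of the TSS), (iii) the
gene's differential expression exceeds 0.5 in |log2 ratio| and (iv) the
relation is inverse: hypomethylated regions pair with upregulated genes and
vice versa (both differences oriented group1 - group2, i.e. LSC - Blast).
Gene-body-only mappings are excluded.  Genes with several signature DMRs get
1-based ordinals by genomic coordinate, rendered "GENE/DMR{n}".
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, DMRecord

log = logging.getLogger("lscsig")

MUTATION_CLASSES = ("upstream", "enzyme", "both", "independent", "unassigned")


@dataclass
class SignatureEntry:
    """One DMR-gene pair of the signature."""

    gene: str
    dmr_ordinal: int
    region: DMRecord
    log2fc: float
    direction: str  # hypo_up | hyper_down
    mutation_class: str = "unassigned"

    @property
    def label(self) -> str:
        return f"{self.gene}/DMR{self.dmr_ordinal}"


def signature_frame(entries) -> pd.DataFrame:
    rows = [
        {
            "gene": e.gene,
            "dmr_label": e.label,
            "region_id": e.region.region_id,
            "chrom": e.region.chrom,
            "start": e.region.start,
            "end": e.region.end,
            "n_probes": e.region.n_probes,
            "context": e.region.context,
            "delta_beta": e.region.value,
            "p_perm": e.region.p_perm,
            "log2fc": e.log2fc,
            "direction": e.direction,
            "mutation_class": e.mutation_class,
        }
        for e in entries
    ]
    cols = ["gene", "dmr_label", "region_id", "chrom", "start", "end", "n_probes",
            "context", "delta_beta", "p_perm", "log2fc", "direction", "mutation_class"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# CpG context annotation


def classify_context(pos: int, chrom: str, islands: pd.DataFrame) -> str:
    """CpG context of a position given a merged, sorted island track.

    inside an island -> island; within 2 kb of an island edge -> shore;
    2-4 kb away -> shelf; farther (or a chromosome without islands) ->
    open_sea.
    """
    sub = islands[islands["chrom"] == chrom]
    if sub.empty:
        return "open_sea"
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    i = bisect.bisect_right(list(starts), pos) - 1
    dist = np.inf
    if i >= 0:
        if pos <= ends[i]:
            return "island"
        dist = pos - ends[i]
    if i + 1 < len(starts):
        dist = min(dist, starts[i + 1] - pos)
    if dist <= 2000:
        return "shore"
    if dist <= 4000:
        return "shelf"
    return "open_sea"


def annotate_contexts(manifest: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    """Fill the manifest context column from an island track (vectorized)."""
    out = manifest.copy()
    contexts = np.full(len(out), "open_sea", dtype=object)
    chrom_arr = out["chrom"].to_numpy()
    pos_arr = out["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        rows = np.flatnonzero(chrom_arr == chrom)
        sub = islands[islands["chrom"] == chrom].sort_values("start")
        if sub.empty:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        pos = pos_arr[rows]
        i = np.searchsorted(starts, pos, side="right") - 1
        prev_end = np.where(i >= 0, ends[np.clip(i, 0, None)], -np.inf)
        inside = (i >= 0) & (pos <= prev_end)
        dist_prev = np.where(i >= 0, pos - prev_end, np.inf)
        nxt = i + 1
        dist_next = np.where(nxt < len(starts),
                             starts[np.clip(nxt, None, len(starts) - 1)] - pos, np.inf)
        dist = np.minimum(dist_prev, dist_next)
        ctx = np.full(len(pos), "open_sea", dtype=object)
        ctx[dist <= 4000] = "shelf"
        ctx[dist <= 2000] = "shore"
        ctx[inside] = "island"
        contexts[rows] = ctx
    out["context"] = contexts
    return out


# ---------------------------------------------------------------------------
# gene mapping


def map_dmr_to_gene(dmr: DMRecord, genes: pd.DataFrame, window: int = 2000
                    ) -> list[tuple[str, str]]:
    """Genes a DMR maps to, with relation 'promoter' or 'gene_body'.

    Promoter: the region overlaps [tss - window, tss + window] (symmetric,
    strand-ignorant).  Gene body: overlaps the gene span but not the promoter
    window.  A DMR may map to several genes.
    """
    sub = genes[genes["chrom"] == dmr.chrom]
    out: list[tuple[str, str]] = []
    for row in sub.itertuples(index=False):
        prom_lo, prom_hi = row.tss - window, row.tss + window
        if dmr.start <= prom_hi and dmr.end >= prom_lo:
            out.append((row.gene, "promoter"))
        elif dmr.start <= row.gene_end and dmr.end >= row.gene_start:
            out.append((row.gene, "gene_body"))
    return out


def differential_expression(expr: pd.DataFrame, samples1, samples2) -> pd.Series:
    """Per-gene mean log2 expression difference, group1 - group2."""
    samples1, samples2 = list(samples1), list(samples2)
    if len(samples1) < 2 or len(samples2) < 2:
        raise DataError("each group needs >= 2 samples")
    missing = (set(samples1) | set(samples2)) - set(expr.columns)
    if missing:
        raise DataError(f"samples missing from expression matrix: {sorted(missing)}")
    sub = expr[samples1 + samples2]
    if not np.isfinite(sub.to_numpy(dtype=float)).all():
        bad = sub.index[~np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)][:5]
        raise DataError(f"missing expression values for genes {list(bad)}")
    return expr[samples1].mean(axis=1) - expr[samples2].mean(axis=1)


# ---------------------------------------------------------------------------
# signature construction


def build_signature(dmrs, diffexpr: pd.Series, genes: pd.DataFrame, *,
                    p_cutoff: float = 0.01, expr_cutoff: float = 0.5,
                    window: int = 2000) -> list[SignatureEntry]:
    """Emit signature entries for DMR-gene pairs passing all four filters.

    Filters: p_perm < p_cutoff; promoter overlap within ``window`` of the
    TSS; |log2fc| > expr_cutoff; inverse methylation-expression relation
    (sign(delta beta) opposite to sign(log2fc)).  A DMR that is promoter for
    gene A and gene-body for gene B counts for A only.  Genes mapped but
    absent from the expression table are skipped with a warning.
    Per-gene ordinals are assigned by genomic coordinate.
    """
    raw: list[tuple[str, DMRecord, float]] = []
    for d in dmrs:
        if not (d.p_perm < p_cutoff):
            continue
        for gene, relation in map_dmr_to_gene(d, genes, window):
            if relation != "promoter":
                continue
            if gene not in diffexpr.index:
                log.warning("signature: gene %s mapped by %s absent from "
                            "expression matrix; skipped", gene, d.region_id)
                continue
            lfc = float(diffexpr.loc[gene])
            if abs(lfc) <= expr_cutoff:
                continue
            if np.sign(lfc) == np.sign(d.value) or d.value == 0 or lfc == 0:
                continue  # not an inverse relation
            raw.append((gene, d, lfc))

    entries: list[SignatureEntry] = []
    by_gene: dict[str, list[tuple[DMRecord, float]]] = {}
    for gene, d, lfc in raw:
        by_gene.setdefault(gene, []).append((d, lfc))
    for gene in sorted(by_gene):
        pairs = sorted(by_gene[gene], key=lambda t: (t[0].chrom, t[0].start, t[0].end))
        for ordinal, (d, lfc) in enumerate(pairs, start=1):
            direction = "hypo_up" if d.value < 0 else "hyper_down"
            entries.append(SignatureEntry(gene=gene, dmr_ordinal=ordinal,
                                          region=d, log2fc=lfc, direction=direction))
    n_genes = len(by_gene)
    log.info("signature: %d entries over %d unique genes", len(entries), n_genes)
    return entries


def methylation_expression_correlation(dmrs, diffexpr: pd.Series,
                                       genes: pd.DataFrame, *,
                                       window: int = 2000) -> pd.DataFrame:
    """Pearson r (and p) of DMR value vs mapped-gene log2fc per CpG context.

    Strata with fewer than 3 pairs, or degenerate (constant) inputs, are
    reported as NA.
    """
    pairs: list[tuple[str, float, float]] = []
    for d in dmrs:
        for gene, relation in map_dmr_to_gene(d, genes, window):
            if relation != "promoter" or gene not in diffexpr.index:
                continue
            pairs.append((d.context or "open_sea", d.value, float(diffexpr.loc[gene])))
    rows = []
    frame = pd.DataFrame(pairs, columns=["context", "value", "log2fc"])
    for ctx in ("island", "shore", "shelf", "open_sea"):
        sub = frame[frame["context"] == ctx]
        if len(sub) < 3 or sub["value"].nunique() == 1 or sub["log2fc"].nunique() == 1:
            rows.append({"context": ctx, "n": len(sub), "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(sub["value"], sub["log2fc"])
        rows.append({"context": ctx, "n": len(sub), "r": r, "p": p})
    return pd.DataFrame(rows)
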