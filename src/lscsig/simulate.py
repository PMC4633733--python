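"""Seeded synthetic data with the statistical structure of the LSC analysis.

The generators emulate 450k-style methylation studies: beta values in [0, 1]
with CpG island / shore / shelf / open-sea strata, planted multi-probe DMRs
(hypo:hyper direction ratio ~91:10 in LSC by default), inverse promoter
methylation-expression coupling, mutation-driven DMR subsets, six normal
haematopoietic stem/progenitor (HSPC) reference classes with two dominant
AML-like cohort clusters (GMP-like and L-MPP-like), and survival times whose
hazard depends on a latent LSC score.  Every generator is deterministic
given its seed and returns a truth table sufficient to score any caller
output without re-reading the generator parameters.

Noise model: Gaussian on logit(beta) with clipping to [0.001, 0.999] before
the logit, which keeps beta in range.  Planted DMRs span 3-8 consecutive
probes of a probe cluster.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dmr import cluster_probes
from .io import DataError, DMRecord, validate_beta_matrix
from .signature import annotate_contexts

log = logging.getLogger("lscsig")

HSPC_CLASSES = ("HSC", "MPP", "L-MPP", "CMP", "GMP", "MEP")
UPSTREAM_GENES = ("NPM1", "ASXL1")
ENZYME_GENES = ("DNMT3A", "TET2")

# mutation-driver mix of planted regions: independent / upstream-only /
# enzyme-only / both (matching a 40:17:16:11 split)
DRIVER_FRACS = {"none": 0.48, "upstream": 0.20, "enzyme": 0.19, "both": 0.13}

_CONTEXT_BASE = {"island": (0.10, 0.30), "shore": (0.30, 0.60),
                 "shelf": (0.40, 0.70), "open_sea": (0.60, 0.85)}


def child_seed(seed: int | None, name: str) -> int | None:
    """Stable per-stage child seed derived from a global seed (below 2^31)."""
    if seed is None:
        return None
    return zlib.crc32(f"{seed}:{name}".encode()) % (2 ** 31)


@dataclass
class PlantedDMR:
    region_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    delta: float                      # signed, group1(LSC) - group2(Blast)
    driver: str                       # none | upstream | enzyme | both
    driver_genes: tuple[str, ...]
    gene: str                         # mapped gene ("" if none)
    relation: str                     # promoter | gene_body
    coupled: bool                     # expression coupled inversely


@dataclass
class SimulationTruth:
    """Ground truth of a generated dataset (sufficient to score callers)."""

    seed: int | None
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    signature_genes: list[tuple[str, str]] = field(default_factory=list)
    class_profiles: dict[str, np.ndarray] = field(default_factory=dict)
    marker_regions: dict[str, list[DMRecord]] = field(default_factory=dict)
    cohort_labels: pd.Series | None = None
    latent_score: pd.Series | None = None
    hazard_coefficient: float = 0.0

    def planted_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "region_id": p.region_id, "chrom": p.chrom, "start": p.start,
            "end": p.end, "n_probes": len(p.probe_ids), "delta": p.delta,
            "driver": p.driver, "driver_genes": ";".join(p.driver_genes),
            "gene": p.gene, "relation": p.relation, "coupled": p.coupled,
        } for p in self.planted_dmrs])

    def score_calls(self, called: list) -> dict:
        """Sensitivity and empirical FDR of a call set vs the planted truth.

        A planted region counts as detected if any called region shares a
        probe with it; a called region is a false positive if it shares no
        probe with any planted region.
        """
        planted_probes = [set(p.probe_ids) for p in self.planted_dmrs]
        all_planted = set().union(*planted_probes) if planted_probes else set()
        detected = [False] * len(planted_probes)
        n_fp = 0
        for c in called:
            probes = set(c.probe_ids)
            if probes & all_planted:
                for i, pp in enumerate(planted_probes):
                    if probes & pp:
                        detected[i] = True
            else:
                n_fp += 1
        n_called = len(called)
        return {
            "sensitivity": (sum(detected) / len(detected)) if detected else float("nan"),
            "fdr": (n_fp / n_called) if n_called else 0.0,
            "n_called": n_called,
            "n_false_positive": n_fp,
            "n_planted": len(planted_probes),
            "n_detected": int(sum(detected)),
        }


# ---------------------------------------------------------------------------
# manifest


def generate_manifest(n_probes: int = 6000, n_islands: int | None = None,
                      seed: int | None = None, n_chroms: int = 2
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Probe manifest, CpG-island track and gene annotation.

    Probes are organized in gene units spaced 50 kb apart across
    ``n_chroms`` chromosomes.  Each unit carries a CpG island around the
    gene's TSS with an 8-probe promoter cluster inside it, shore and shelf
    probes flanking the island, a 6-probe open-sea cluster in the gene body
    beyond 2 kb of the TSS, and any remaining probes as isolated open-sea
    sites - so every context stratum is represented and every gene has both
    promoter and gene-body probes.
    """
    if n_probes < 10:
        raise DataError("n_probes must be >= 10")
    if n_islands is None:
        n_islands = max(2, n_probes // 30)
    if n_islands < 2:
        raise DataError("need >= 2 islands (units) to span 2+ chromosomes")
    n_units = n_islands
    rng = np.random.default_rng(seed)
    # promoter/gene-body cluster sizes, drawn uniformly on 3..8 per unit
    prom_sizes = rng.integers(3, 9, n_units)
    body_sizes = rng.integers(3, 9, n_units)
    fixed_total = int(prom_sizes.sum() + body_sizes.sum() + 4 * n_units)
    if n_probes < fixed_total:
        raise DataError(
            f"{n_probes} probes cannot cover all context strata over "
            f"{n_units} units (need >= {fixed_total}); reduce n_islands")
    extra_total = n_probes - fixed_total
    extras = np.full(n_units, extra_total // n_units)
    extras[: extra_total % n_units] += 1
    if extras.max() > 44:
        raise DataError("too many probes per unit; increase n_islands")
    probes: list[tuple[str, int]] = []        # (chrom, pos)
    islands_rows, gene_rows = [], []
    for u in range(n_units):
        chrom = f"chr{(u % n_chroms) + 1}"
        a = 100_000 + (u // n_chroms) * 50_000
        islands_rows.append((chrom, a, a + 600))
        tss = a + 300
        gene_rows.append((f"GENE{u + 1:04d}", chrom, "+", tss, a, a + 12_000))
        # promoter cluster (island, within 2 kb of TSS)
        for j in range(int(prom_sizes[u])):
            probes.append((chrom, a + 60 + j * 70 + int(rng.integers(0, 8))))
        # shores / shelves
        probes.append((chrom, a - 1_200 + int(rng.integers(0, 50))))
        probes.append((chrom, a + 1_500 + int(rng.integers(0, 50))))
        probes.append((chrom, a - 3_500 + int(rng.integers(0, 50))))
        probes.append((chrom, a + 3_400 + int(rng.integers(0, 50))))
        # gene-body open-sea cluster (> 2 kb from TSS, inside gene span)
        for j in range(int(body_sizes[u])):
            probes.append((chrom, a + 5_000 + j * 80 + int(rng.integers(0, 10))))
        # isolated open-sea probes
        for j in range(int(extras[u])):
            probes.append((chrom, a + 14_000 + j * 700 + int(rng.integers(0, 80))))

    manifest = pd.DataFrame(probes, columns=["chrom", "pos"])
    manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    manifest.insert(0, "probe_id", [f"cg{i + 1:07d}" for i in range(len(manifest))])
    manifest["snp_flag"] = rng.random(len(manifest)) < 0.02
    islands = pd.DataFrame(islands_rows, columns=["chrom", "start", "end"])
    islands = islands.sort_values(["chrom", "start"]).reset_index(drop=True)
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "strand", "tss",
                                             "gene_start", "gene_end"])
    manifest = annotate_contexts(manifest, islands)
    manifest = manifest[["probe_id", "chrom", "pos", "context", "snp_flag"]]
    return manifest, islands, genes


# ---------------------------------------------------------------------------
# plantable sites


def _plantable_clusters(manifest: pd.DataFrame, genes: pd.DataFrame,
                        maxgap: int = 500, promoter_window: int = 2000
                        ) -> list[dict]:
    """Probe clusters of >= 3 members, annotated with their gene relation."""
    order = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cl = cluster_probes(order, maxgap)
    sites = []
    gene_by_chrom = {c: g for c, g in genes.groupby("chrom")}
    bounds = np.flatnonzero(np.r_[True, cl[1:] != cl[:-1]])
    for s, e in zip(bounds, np.r_[bounds[1:], len(cl)]):
        if e - s < 3:
            continue
        idx = np.arange(s, e)
        sub = order.iloc[idx]
        chrom = sub["chrom"].iloc[0]
        lo, hi = int(sub["pos"].min()), int(sub["pos"].max())
        gene, relation = "", ""
        for row in gene_by_chrom.get(chrom, pd.DataFrame()).itertuples(index=False):
            if lo <= row.tss + promoter_window and hi >= row.tss - promoter_window:
                gene, relation = row.gene, "promoter"
                break
            if lo <= row.gene_end and hi >= row.gene_start:
                gene, relation = row.gene, "gene_body"
        sites.append({"chrom": chrom, "rows": idx,
                      "probe_ids": tuple(sub["probe_id"]),
                      "pos": sub["pos"].to_numpy(),
                      "gene": gene, "relation": relation})
    return sites


def _base_means(manifest: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    base = np.empty(len(manifest))
    ctx = manifest["context"].to_numpy()
    for c, (lo, hi) in _CONTEXT_BASE.items():
        m = ctx == c
        base[m] = rng.uniform(lo, hi, m.sum())
    return base


def _logit_noise_beta(mu: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """beta = expit(logit(clip(mu)) + N(0, sd)); clip keeps logit finite."""
    l = logit(np.clip(mu, 0.001, 0.999))
    return expit(l + rng.normal(0.0, sd, size=mu.shape))


# ---------------------------------------------------------------------------
# two-group (LSC vs Blast) study


def _allocate(n: int, fracs: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of n items to categories (order stable)."""
    raw = {k: n * f for k, f in fracs.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    out: list[str] = []
    for k, c in counts.items():
        out.extend([k] * c)
    return out


def generate_two_group_study(manifest: pd.DataFrame, islands: pd.DataFrame,
                             genes: pd.DataFrame, *,
                             n_lsc: int = 20, n_blast: int = 24,
                             n_planted: int = 200, frac_hypo: float = 0.914,
                             delta_range: tuple[float, float] = (0.2, 0.3),
                             noise_sd_logit: float = 0.5,
                             coupled_fraction: float = 0.7,
                             coupling_log2: float = 1.0,
                             expr_noise_sd: float = 0.5,
                             caller_cutoff: float = 0.1,
                             seed: int | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Two-group (LSC vs Blast) methylation + expression study with planted DMRs.

    Returns (beta, expression, sample table, truth).  Planted regions occupy
    whole probe clusters (3-8 consecutive probes, uniform by construction of
    the manifest); round(frac_hypo * n_planted) of them are hypomethylated
    in the LSC group (delta = LSC - Blast < 0), the rest hypermethylated.
    Coupled planted promoter DMRs shift the mapped gene's expression by
    ``coupling_log2`` in the inverse direction.  Each planted region carries
    a mutation-driver label (none/upstream/enzyme/both, allocated by
    ``DRIVER_FRACS``) consumed by :func:`generate_mutation_cohort`; the
    two-group matrices themselves carry no genotype effects, mirroring a
    design where mutation contrasts come from a separate cohort.
    """
    if not (0.0 <= frac_hypo <= 1.0):
        raise DataError("frac_hypo must be in [0, 1]")
    if delta_range[1] < caller_cutoff:
        log.warning("planted |delta| below the caller cutoff %.3g: detection "
                    "power will be ~0", caller_cutoff)
    rng = np.random.default_rng(seed)
    order = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    sites = _plantable_clusters(order, genes)
    if n_planted > len(sites):
        raise DataError(f"cannot plant {n_planted} DMRs: only {len(sites)} "
                        "plantable probe clusters")
    chosen = rng.choice(len(sites), size=n_planted, replace=False)

    base = _base_means(order, rng)
    sample_ids = ([f"LSC{i + 1:02d}" for i in range(n_lsc)]
                  + [f"BLAST{i + 1:02d}" for i in range(n_blast)])
    group = np.array(["LSC"] * n_lsc + ["Blast"] * n_blast)

    n_hypo = int(round(frac_hypo * n_planted))
    signs = np.array([-1.0] * n_hypo + [1.0] * (n_planted - n_hypo))
    rng.shuffle(signs)
    drivers = _allocate(n_planted, DRIVER_FRACS)
    rng.shuffle(drivers)

    mu = np.tile(base[:, None], (1, len(sample_ids)))
    planted: list[PlantedDMR] = []
    for k, si in enumerate(chosen):
        site = sites[si]
        rows = site["rows"]
        delta = signs[k] * rng.uniform(*delta_range)
        mid = rng.uniform(0.40, 0.60, size=len(rows))
        mu[rows, :n_lsc] = (mid + delta / 2)[:, None]
        mu[rows, n_lsc:] = (mid - delta / 2)[:, None]
        driver = drivers[k]
        if driver == "upstream":
            dgenes = (str(rng.choice(UPSTREAM_GENES)),)
        elif driver == "enzyme":
            dgenes = (str(rng.choice(ENZYME_GENES)),)
        elif driver == "both":
            dgenes = (str(rng.choice(UPSTREAM_GENES)), str(rng.choice(ENZYME_GENES)))
        else:
            dgenes = ()
        coupled = site["relation"] == "promoter" and rng.random() < coupled_fraction
        planted.append(PlantedDMR(
            region_id=f"planted_{k + 1:04d}", chrom=site["chrom"],
            start=int(site["pos"][0]), end=int(site["pos"][-1]),
            probe_ids=site["probe_ids"],
            delta=float(delta), driver=driver, driver_genes=dgenes,
            gene=site["gene"], relation=site["relation"], coupled=coupled))

    mu = np.clip(mu, 0.02, 0.98)
    beta = pd.DataFrame(_logit_noise_beta(mu, noise_sd_logit, rng),
                        index=order["probe_id"], columns=sample_ids)
    validate_beta_matrix(beta)

    # expression: genes x samples, coupled genes shifted inversely in LSC
    expr_mu = np.tile(rng.uniform(5.0, 9.0, size=len(genes))[:, None],
                      (1, len(sample_ids)))
    gene_index = {g: i for i, g in enumerate(genes["gene"])}
    signature_genes: list[tuple[str, str]] = []
    for p in planted:
        if p.coupled and p.gene in gene_index:
            gi = gene_index[p.gene]
            shift = -np.sign(p.delta) * coupling_log2
            expr_mu[gi, :n_lsc] += shift
            signature_genes.append((p.gene, "up" if shift > 0 else "down"))
    expr = pd.DataFrame(expr_mu + rng.normal(0.0, expr_noise_sd, expr_mu.shape),
                        index=genes["gene"], columns=sample_ids)

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "group": group,
        "patient_id": [f"PT{i + 1:02d}" for i in range(len(sample_ids))],
        "age": np.round(rng.normal(55, 12, len(sample_ids)), 1),
    })
    truth = SimulationTruth(seed=seed, planted_dmrs=planted,
                            signature_genes=signature_genes)
    return beta, expr, samples, truth


def generate_mutation_cohort(manifest: pd.DataFrame, truth: SimulationTruth, *,
                             n_samples: int = 40, mutation_delta: float = 0.25,
                             noise_sd_logit: float = 0.5,
                             active_genes: tuple[str, ...] | None = None,
                             seed: int | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AML cohort with genotype-driven methylation at driver-labelled regions.

    For each mutation gene, exactly half the cohort carries the mutation;
    at every planted region the gene drives (per the truth's driver labels),
    carriers differ from wild type by ``mutation_delta`` beta units in the
    direction of the region's planted delta.  Returns (beta, sample table
    with ``mut_<GENE>`` genotype columns).  Built on the same manifest as
    the discovery study so region overlap is probe-exact.  ``active_genes``
    restricts which mutations actually shift methylation (all by default);
    genotype columns are always generated for every mutation gene.
    """
    if n_samples < 4:
        raise DataError("n_samples must be >= 4")
    rng = np.random.default_rng(seed)
    order = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    base = _base_means(order, rng)
    sample_ids = [f"MUT{i + 1:03d}" for i in range(n_samples)]
    mut_genes = list(UPSTREAM_GENES + ENZYME_GENES)
    geno = pd.DataFrame(0, index=sample_ids, columns=[f"mut_{g}" for g in mut_genes])
    for g in mut_genes:
        carriers = rng.permutation(n_samples)[: n_samples // 2]
        geno.iloc[carriers, geno.columns.get_loc(f"mut_{g}")] = 1

    pos_of = pd.Series(np.arange(len(order)), index=order["probe_id"])
    mu = np.tile(base[:, None], (1, n_samples))
    for p in truth.planted_dmrs:
        rows = pos_of[list(p.probe_ids)].to_numpy()
        mid = rng.uniform(0.40, 0.60, size=len(rows))
        mu[rows] = mid[:, None]
        for dg in p.driver_genes:
            if active_genes is not None and dg not in active_genes:
                continue
            carr = geno[f"mut_{dg}"].to_numpy() == 1
            shift = np.sign(p.delta) * mutation_delta / 2
            mu[np.ix_(rows, np.flatnonzero(carr))] += shift
            mu[np.ix_(rows, np.flatnonzero(~carr))] -= shift
    mu = np.clip(mu, 0.02, 0.98)
    beta = pd.DataFrame(_logit_noise_beta(mu, noise_sd_logit, rng),
                        index=order["probe_id"], columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "group": "AML",
                            "patient_id": sample_ids})
    samples = pd.concat([samples, geno.reset_index(drop=True)], axis=1)
    return beta, samples


# ---------------------------------------------------------------------------
# reference classes + clinical cohort


def generate_reference_and_cohort(manifest: pd.DataFrame, islands: pd.DataFrame,
                                  genes: pd.DataFrame, *,
                                  classes: tuple[str, ...] = HSPC_CLASSES,
                                  n_per_class: int = 5, n_cohort: int = 500,
                                  cluster_mix: dict[str, float] | None = None,
                                  hazard_coefficient: float = 0.7,
                                  marker_delta: float = 0.3,
                                  markers_per_class: int = 8,
                                  noise_sd_logit: float = 0.5,
                                  n_signature_genes: int = 40,
                                  expr_noise_sd: float = 0.5,
                                  baseline_hazard: float = 1 / 600,
                                  seed: int | None = None):
    """Reference HSPC profiles plus an AML cohort with survival.

    Returns (reference beta, cohort beta, cohort expression, sample table,
    truth).  Each class gets ``markers_per_class`` marker regions (>= 3
    probes) where its mean beta is shifted by +/- ``marker_delta``; cohort
    samples are drawn from class profiles per ``cluster_mix`` (default GMP
    0.77 / L-MPP 0.15 / CMP 0.08).  Survival times are exponential with
    log-hazard = log(baseline) + hazard_coefficient * latent LSC score,
    with independent censoring; covariates are generated with a configured
    association to the cluster.
    """
    if n_per_class < 2:
        raise DataError("n_per_class must be >= 2 (class sd undefined)")
    if cluster_mix is None:
        cluster_mix = {"GMP": 0.77, "L-MPP": 0.15, "CMP": 0.08}
    if abs(sum(cluster_mix.values()) - 1.0) > 1e-9:
        raise DataError("cluster_mix proportions must sum to 1")
    unknown = set(cluster_mix) - set(classes)
    if unknown:
        raise DataError(f"cluster_mix classes not in reference set: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    order = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    sites = _plantable_clusters(order, genes)
    need = markers_per_class * len(classes)
    if need > len(sites):
        raise DataError(f"need {need} marker clusters, only {len(sites)} available")
    chosen = rng.choice(len(sites), size=need, replace=False)

    base = _base_means(order, rng)
    profiles = {c: base.copy() for c in classes}
    marker_regions: dict[str, list[DMRecord]] = {c: [] for c in classes}
    for i, c in enumerate(classes):
        for j in range(markers_per_class):
            site = sites[chosen[i * markers_per_class + j]]
            rows = site["rows"]
            mid = rng.uniform(0.35, 0.65, size=len(rows))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for cc in classes:
                profiles[cc][rows] = mid
            profiles[c][rows] = mid + sign * marker_delta
            marker_regions[c].append(DMRecord(
                region_id=f"marker_{c}_{j + 1:02d}", chrom=site["chrom"],
                start=int(site["pos"][0]), end=int(site["pos"][-1]),
                probe_ids=site["probe_ids"], value=sign * marker_delta,
                area=abs(marker_delta) * len(rows)))

    # reference samples
    ref_cols, ref_vals, ref_rows = [], [], []
    for c in classes:
        for r in range(n_per_class):
            sid = f"{c}_r{r + 1}"
            ref_cols.append(sid)
            ref_vals.append(_logit_noise_beta(profiles[c], noise_sd_logit, rng))
            ref_rows.append({"sample_id": sid, "group": c, "patient_id": sid})
    ref_beta = pd.DataFrame(np.column_stack(ref_vals), index=order["probe_id"],
                            columns=ref_cols)

    # cohort
    labels = np.array(_allocate(n_cohort, cluster_mix))
    rng.shuffle(labels)
    cohort_ids = [f"TCGA{i + 1:04d}" for i in range(n_cohort)]
    score_mu = {c: 0.3 for c in classes} | {"GMP": 0.0, "L-MPP": 1.0}
    z = np.array([rng.normal(score_mu[c], 0.5) for c in labels])
    cohort_vals = np.column_stack([
        _logit_noise_beta(profiles[c], noise_sd_logit, rng) for c in labels])
    cohort_beta = pd.DataFrame(cohort_vals, index=order["probe_id"], columns=cohort_ids)

    # expression of signature genes driven by the latent score
    sig_genes = list(genes["gene"].iloc[:n_signature_genes])
    directions = np.where(rng.random(len(sig_genes)) < 0.7, 1.0, -1.0)
    loadings = directions * rng.uniform(0.5, 1.5, len(sig_genes))
    expr_mu = rng.uniform(5.0, 9.0, len(sig_genes))[:, None] + loadings[:, None] * z[None, :]
    cohort_expr = pd.DataFrame(expr_mu + rng.normal(0, expr_noise_sd, expr_mu.shape),
                               index=sig_genes, columns=cohort_ids)
    signature_genes = [(g, "up" if d > 0 else "down")
                       for g, d in zip(sig_genes, directions)]

    # survival with independent censoring
    rate = baseline_hazard * np.exp(hazard_coefficient * z)
    event_time = rng.exponential(1.0 / rate)
    censor_time = np.minimum(rng.exponential(1200, n_cohort), 2000)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    risk = np.empty(n_cohort, dtype=object)
    for i, c in enumerate(labels):
        p = (0.10, 0.30, 0.60) if c == "L-MPP" else (0.25, 0.55, 0.20)
        risk[i] = rng.choice(("low", "intermediate", "high"), p=p)
    npm1 = (rng.random(n_cohort) < np.where(labels == "GMP", 0.40, 0.15)).astype(int)
    flt3 = (rng.random(n_cohort) < np.where(labels == "GMP", 0.35, 0.15)).astype(int)
    dnmt3a = (rng.random(n_cohort) < 0.25).astype(int)

    samples = pd.DataFrame({
        "sample_id": cohort_ids,
        "group": "AML",
        "patient_id": cohort_ids,
        "age": np.round(50 + 5 * z + rng.normal(0, 10, n_cohort), 1),
        "cytogenetic_risk": risk,
        "mut_NPM1": npm1,
        "mut_FLT3": flt3,
        "mut_DNMT3A": dnmt3a,
        "os_time": np.round(os_time, 1),
        "os_event": os_event,
    })
    ref_samples = pd.DataFrame(ref_rows)
    sample_table = pd.concat([ref_samples, samples], ignore_index=True)

    truth = SimulationTruth(
        seed=seed,
        signature_genes=signature_genes,
        class_profiles=profiles,
        marker_regions=marker_regions,
        cohort_labels=pd.Series(labels, index=cohort_ids, name="true_class"),
        latent_score=pd.Series(z, index=cohort_ids, name="latent_lsc_score"),
        hazard_coefficient=hazard_coefficient,
    )
    return ref_beta, cohort_beta, cohort_expr, sample_table, truth


def simulate_survival_cohort(n: int = 500, hr: float = 2.0,
                             baseline_hazard: float = 1 / 600,
                             censor_scale: float = 1500.0,
                             seed: int | None = None) -> pd.DataFrame:
    """Two-group exponential-survival cohort with clinical covariates.

    Half the cohort is in the 'high' stratum whose hazard is ``hr`` times
    the baseline; censoring is independent exponential.  Age, cytogenetic
    risk and mutation covariates are generated independently of the hazard,
    so any of them is a valid null covariate.
    """
    rng = np.random.default_rng(seed)
    high = np.zeros(n, dtype=int)
    high[rng.permutation(n)[: n // 2]] = 1
    rate = baseline_hazard * np.where(high == 1, hr, 1.0)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(censor_scale, n)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "stratum": np.where(high == 1, "high", "low"),
        "group_indicator": high,
        "age": np.round(rng.normal(55, 12, n), 1),
        "cytogenetic_risk": rng.choice(("low", "intermediate", "high"),
                                       size=n, p=(0.25, 0.55, 0.20)),
        "mut_NPM1": rng.integers(0, 2, n),
        "mut_FLT3": rng.integers(0, 2, n),
        "os_time": np.round(os_time, 1),
        "os_event": os_event,
    })
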