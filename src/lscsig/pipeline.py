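"""End-to-end orchestration of the synthetic demo analysis.

``run_pipeline`` composes the stages simulate -> call-dmrs -> build-signature
-> classify-mutations -> fit-profiles/assign -> survival on files in an
output directory, with one top-level seed (per-stage child seeds derived by
stable hashing of the stage name) and a run manifest recording the config
hash, seeds, input digests and per-stage outputs.  Each stage is a pure
function of the previous stage's files; a failing stage halts the run with
its name while earlier outputs are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import Config
from .dmr import BumpHunter, summarize_dmrs
from .identity import ProfileClassifier, assign_cohort, lsc_expression_score
from .io import dmr_frame, write_beta_matrix, write_dmr_bed, write_expression_matrix, write_manifest
from .mutations import classify_signature, mutation_dmrs
from .signature import build_signature, differential_expression, signature_frame
from .simulate import (UPSTREAM_GENES, child_seed, generate_manifest,
                       generate_mutation_cohort, generate_reference_and_cohort,
                       generate_two_group_study)
from .survival import cox_multivariate, km_logrank

log = logging.getLogger("lscsig")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Config, outdir, *, n_probes: int = 3000,
                 n_planted: int = 60, n_cohort: int = 200) -> dict:
    """Run the full demo pipeline on synthetic data; returns the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest_entry: dict = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16],
        "seed": seed,
        "stages": {},
    }

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest_entry["stages"][stage] = {
            "seed": child_seed(seed, stage),
            "outputs": {k: {"path": str(p), "sha256": _digest(p)}
                        for k, p in paths.items()},
        }

    stage = "simulate"
    try:
        probes, islands, genes = generate_manifest(
            n_probes=n_probes, seed=child_seed(seed, "manifest"))
        beta, expr, samples, truth = generate_two_group_study(
            probes, islands, genes, n_planted=n_planted,
            seed=child_seed(seed, stage))
        paths = {
            "manifest": out / "manifest.tsv", "beta": out / "beta.tsv",
            "expression": out / "expression.tsv", "samples": out / "samples.tsv",
            "truth": out / "truth_planted.csv",
        }
        write_manifest(probes, paths["manifest"])
        write_beta_matrix(beta, paths["beta"])
        write_expression_matrix(expr, paths["expression"])
        samples.to_csv(paths["samples"], sep="\t", index=False)
        truth.planted_frame().to_csv(paths["truth"], index=False)
        record(stage, paths)

        stage = "call-dmrs"
        lsc = samples.loc[samples["group"] == "LSC", "sample_id"].tolist()
        blast = samples.loc[samples["group"] == "Blast", "sample_id"].tolist()
        model = BumpHunter(beta, probes, lsc, blast,
                           cutoff=config.delta_cutoff, maxgap=config.maxgap,
                           smooth_window=config.smooth_window,
                           min_probes=config.min_probes)
        res = model.fit(n_permutations=config.n_permutations,
                        seed=child_seed(seed, stage))
        paths = {"dmrs": out / "dmrs.csv", "bed": out / "dmrs.bed",
                 "summary": out / "dmr_summary.csv"}
        res.table.to_csv(paths["dmrs"], index=False)
        sig_dmrs = res.significant(config.p_cutoff)
        write_dmr_bed(sig_dmrs, paths["bed"])
        summarize_dmrs(sig_dmrs).to_csv(paths["summary"], index=False)
        record(stage, paths)

        stage = "build-signature"
        diffexpr = differential_expression(expr, lsc, blast)
        signature = build_signature(sig_dmrs, diffexpr, genes,
                                    p_cutoff=config.p_cutoff,
                                    expr_cutoff=config.expr_cutoff,
                                    window=config.promoter_window)
        paths = {"signature": out / "signature.csv"}
        signature_frame(signature).to_csv(paths["signature"], index=False)
        record(stage, paths)

        stage = "classify-mutations"
        mut_beta, mut_samples = generate_mutation_cohort(
            probes, truth, seed=child_seed(seed, stage))
        mut_sets = {}
        for g in ("NPM1", "ASXL1", "DNMT3A", "TET2"):
            mut_sets[g] = mutation_dmrs(
                mut_beta, mut_samples, g, manifest=probes, p_cutoff=config.p_cutoff,
                n_permutations=config.n_permutations,
                seed=child_seed(seed, f"{stage}:{g}"),
                cutoff=config.delta_cutoff, maxgap=config.maxgap,
                smooth_window=config.smooth_window)
        counts = classify_signature(
            signature,
            [mut_sets[g] for g in UPSTREAM_GENES],
            [mut_sets[g] for g in ("DNMT3A", "TET2")])
        paths = {"signature_classified": out / "signature_classified.csv",
                 "mutation_counts": out / "mutation_class_counts.csv"}
        signature_frame(signature).to_csv(paths["signature_classified"], index=False)
        counts.rename("n_dmrs").to_csv(paths["mutation_counts"])
        record(stage, paths)

        stage = "assign-identity"
        ref_beta, cohort_beta, cohort_expr, cohort_samples, ctruth = \
            generate_reference_and_cohort(probes, islands, genes,
                                          n_cohort=n_cohort,
                                          seed=child_seed(seed, stage))
        panel = [r for regs in ctruth.marker_regions.values() for r in regs]
        clf = ProfileClassifier.from_reference(
            ref_beta, cohort_samples, list(ctruth.marker_regions), panel,
            sd_floor=config.sd_floor)
        assignments, composition = assign_cohort(cohort_beta, clf, panel)
        paths = {"assignments": out / "identity_assignments.csv",
                 "composition": out / "identity_composition.csv"}
        assignments.to_csv(paths["assignments"], index=False)
        composition.rename("fraction").to_csv(paths["composition"])
        record(stage, paths)

        stage = "survival"
        cohort = cohort_samples[cohort_samples["group"] == "AML"].reset_index(drop=True)
        score = lsc_expression_score(
            cohort_expr, [g for g, _ in ctruth.signature_genes],
            up_genes=[g for g, d in ctruth.signature_genes if d == "up"])
        records = cohort.merge(score, on="sample_id")
        km = km_logrank(records, "stratum")
        cox = cox_multivariate(records, ["stratum", "age", "cytogenetic_risk",
                                         "mut_NPM1", "mut_FLT3"])
        paths = {"cox": out / "survival_cox.csv",
                 "logrank": out / "survival_logrank.json"}
        cox.to_csv(paths["cox"], index=False)
        paths["logrank"].write_text(json.dumps(
            {"statistic": km.statistic, "p_value": km.p_value}, indent=2))
        record(stage, paths)
    except Exception:
        log.error("pipeline failed at stage %r; earlier outputs preserved in %s",
                  stage, out)
        raise

    (out / "run_manifest.json").write_text(json.dumps(manifest_entry, indent=2))
    return manifest_entry
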