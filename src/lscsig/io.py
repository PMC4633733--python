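"""Core data contracts and file I/O.

All tables are exchanged as plain TSV/CSV; genomic intervals are 1-based
inclusive in memory and BED (0-based half-open) on disk.  Methylation is
carried as beta values (methylated fraction, in [0, 1]) in a probes x samples
DataFrame; expression as normalized log2 values in a genes x samples
DataFrame.

Validation is strict and fail-fast: out-of-range or missing beta values,
duplicated identifiers and malformed manifests raise :class:`DataError`
naming the offending rows rather than being silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("island", "shore", "shelf", "open_sea")

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "context", "snp_flag"]
GENE_COLUMNS = ["gene", "chrom", "strand", "tss", "gene_start", "gene_end"]
ISLAND_COLUMNS = ["chrom", "start", "end"]


class DataError(ValueError):
    """Raised when an input table violates a data contract."""


@dataclass
class DMRecord:
    """A called differentially methylated region.

    Coordinates are 1-based inclusive.  ``value`` is the mean smoothed
    group difference (group1 - group2, beta units) over member probes and
    ``area`` the sum of absolute smoothed differences; ``direction``
    is fixed by the sign of ``value``.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    value: float
    area: float
    p_perm: float = float("nan")
    fwer: float = float("nan")
    p_bh: float = float("nan")
    context: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"{self.region_id}: start {self.start} > end {self.end}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def direction(self) -> str:
        return "group1_gt_group2" if self.value > 0 else "group2_gt_group1"


def dmr_frame(dmrs: Sequence[DMRecord]) -> pd.DataFrame:
    """Tabulate DMRecords, one row per region (empty frame for no regions)."""
    rows = [
        {
            "region_id": d.region_id,
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "n_probes": d.n_probes,
            "value": d.value,
            "area": d.area,
            "direction": d.direction,
            "p_perm": d.p_perm,
            "p_bh": d.p_bh,
            "fwer": d.fwer,
            "context": d.context,
        }
        for d in dmrs
    ]
    cols = [
        "region_id", "chrom", "start", "end", "n_probes", "value", "area",
        "direction", "p_perm", "p_bh", "fwer", "context",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# matrices


def _check_unique(index: pd.Index, what: str, where: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise DataError(f"duplicate {what} in {where}: {dups}")


def validate_beta_matrix(beta: pd.DataFrame, name: str = "beta matrix") -> pd.DataFrame:
    """Validate a probes x samples beta-value matrix.

    All values must be finite and in [0, 1]; probe and sample ids unique.
    Missing values are disallowed (no imputation) and reported by probe.
    """
    _check_unique(beta.index, "probe ids", name)
    _check_unique(beta.columns, "sample ids", name)
    values = beta.to_numpy(dtype=float, copy=False)
    bad = ~np.isfinite(values)
    if bad.any():
        probes = beta.index[bad.any(axis=1)].tolist()[:5]
        raise DataError(f"{name}: non-finite/missing beta values at probes {probes}")
    out = (values < 0.0) | (values > 1.0)
    if out.any():
        i, j = np.argwhere(out)[0]
        raise DataError(
            f"{name}: beta value {values[i, j]!r} out of [0, 1] at "
            f"probe {beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    return beta


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a TSV beta matrix (first column probe ids, header sample ids)."""
    try:
        beta = pd.read_csv(path, sep="\t", index_col=0,
                           float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"{path}: cannot parse beta matrix: {exc}") from exc
    non_numeric = beta.columns[[not np.issubdtype(dt, np.number) for dt in beta.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = beta[col][pd.to_numeric(beta[col], errors="coerce").isna()]
        raise DataError(
            f"{path}: non-numeric value {bad.iloc[0]!r} at probe {bad.index[0]!r}, "
            f"sample {col!r}"
        )
    return validate_beta_matrix(beta, name=str(path))


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    validate_beta_matrix(beta)
    # %.17g guarantees bitwise value round-trip through text
    beta.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a TSV log2 expression matrix (genes x samples)."""
    expr = pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")
    _check_unique(expr.index, "gene ids", str(path))
    _check_unique(expr.columns, "sample ids", str(path))
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise DataError(f"{path}: non-finite expression values")
    return expr


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


# ---------------------------------------------------------------------------
# manifest / annotation tables


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise DataError(f"probe manifest missing columns {missing}")
    _check_unique(pd.Index(manifest["probe_id"]), "probe ids", "manifest")
    if (manifest["pos"] < 1).any():
        raise DataError("manifest positions must be >= 1 (1-based)")
    bad_ctx = set(manifest["context"]) - set(CONTEXTS)
    if bad_ctx:
        raise DataError(f"unknown probe contexts {sorted(bad_ctx)}")
    return manifest


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, sep="\t"))


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest).to_csv(path, sep="\t", index=False)


def merge_islands(islands: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent CpG-island intervals per chromosome."""
    if (islands["start"] > islands["end"]).any():
        raise DataError("island intervals with start > end")
    merged: list[tuple[str, int, int]] = []
    for chrom, grp in islands.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s <= cur_e + 1:
                cur_e = max(cur_e, int(e))
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=ISLAND_COLUMNS)


def read_islands(path) -> pd.DataFrame:
    return merge_islands(pd.read_csv(path, sep="\t"))


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise DataError(f"gene annotation missing columns {missing}")
    if (genes["gene_start"] > genes["gene_end"]).any():
        raise DataError("gene annotation with gene_start > gene_end")
    inside = (genes["tss"] >= genes["gene_start"]) & (genes["tss"] <= genes["gene_end"])
    if not inside.all():
        bad = genes.loc[~inside, "gene"].tolist()[:5]
        raise DataError(f"TSS outside gene span for {bad}")
    return genes


def read_genes(path) -> pd.DataFrame:
    return validate_genes(pd.read_csv(path, sep="\t"))


def validate_sample_table(samples: pd.DataFrame, beta: pd.DataFrame | None = None) -> pd.DataFrame:
    if "sample_id" not in samples.columns:
        raise DataError("sample table missing 'sample_id'")
    _check_unique(pd.Index(samples["sample_id"]), "sample ids", "sample table")
    for col in mutation_columns(samples):
        vals = set(samples[col].dropna().unique())
        if not vals <= {0, 1}:
            raise DataError(f"mutation column {col} not binary: {sorted(vals)}")
    if "os_time" in samples.columns:
        times = samples["os_time"].dropna()
        if (times < 0).any():
            raise DataError("negative survival times")
    if beta is not None:
        missing = set(samples["sample_id"]) - set(beta.columns)
        if missing:
            raise DataError(f"sample ids absent from beta matrix: {sorted(missing)[:5]}")
    return samples


def mutation_columns(samples: pd.DataFrame) -> list[str]:
    """Columns encoding mutation genotypes, named ``mut_<GENE>``."""
    return [c for c in samples.columns if c.startswith("mut_")]


def read_sample_table(path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# BED output


def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return start_1based - 1, end_1based


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def write_dmr_bed(dmrs: Sequence[DMRecord], path) -> None:
    """Write DMRs as BED6: name = region id, score = round(1000*min(1, area))."""
    with open(path, "w") as fh:
        for d in dmrs:
            b_start, b_end = to_bed_interval(d.start, d.end)
            score = int(round(1000 * min(1.0, d.area)))
            fh.write(f"{d.chrom}\t{b_start}\t{b_end}\t{d.region_id}\t{score}\t.\n")
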