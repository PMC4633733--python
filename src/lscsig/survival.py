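"""Survival stratification: Kaplan-Meier / log-rank and multivariate Cox.

Cohort records carry overall-survival time (days) and event flags plus the
clinical covariates used throughout: a two-level stratum (LSC-like vs
Blast-like, or high vs low LSC expression score), age as a continuous
variable, cytogenetic risk dummy-coded as intermediate-vs-low and
high-vs-low, and mutation indicators coded present/absent (1/0).  Fits are
backed by lifelines (Efron handling of tied event times).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import DataError

log = logging.getLogger("lscsig")

RISK_LEVELS = ("low", "intermediate", "high")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("os_time", "os_event"):
        if col not in records.columns:
            raise DataError(f"cohort records missing {col!r}")
    if (records["os_time"] < 0).any():
        raise DataError("negative survival times")
    if not set(records["os_event"].unique()) <= {0, 1}:
        raise DataError("os_event must be 0/1")
    return records


@dataclass
class KMResult:
    """Per-stratum Kaplan-Meier fits with a two-sided log-rank test."""

    fitters: dict[str, KaplanMeierFitter]
    statistic: float
    p_value: float

    def summary(self) -> str:
        lines = [f"log-rank chi2 = {self.statistic:.4g}, p = {self.p_value:.3g}"]
        for name, kmf in self.fitters.items():
            lines.append(f"  {name}: n = {kmf.event_observed.shape[0]}, "
                         f"median survival = {kmf.median_survival_time_}")
        return "\n".join(lines)


def km_logrank(records: pd.DataFrame, stratum_field: str) -> KMResult:
    """Product-limit curves per stratum and the log-rank test across strata."""
    _check_records(records)
    strata = records[stratum_field].unique()
    if len(strata) < 2:
        raise DataError(f"need >= 2 strata in {stratum_field!r}, found {len(strata)}")
    fitters = {}
    for name, grp in records.groupby(stratum_field):
        kmf = KaplanMeierFitter(label=str(name))
        kmf.fit(grp["os_time"], event_observed=grp["os_event"])
        fitters[str(name)] = kmf
    lr = multivariate_logrank_test(records["os_time"], records[stratum_field],
                                   records["os_event"])
    return KMResult(fitters=fitters, statistic=float(lr.test_statistic),
                    p_value=float(lr.p_value))


def _design_matrix(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Build the Cox design: risk as two dummies vs low, strings factorized."""
    X = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov == "cytogenetic_risk":
            risk = records[cov]
            bad = set(risk.dropna().unique()) - set(RISK_LEVELS)
            if bad:
                raise DataError(f"unknown cytogenetic risk levels {sorted(bad)}")
            X["risk_intermediate_vs_low"] = (risk == "intermediate").astype(float)
            X["risk_high_vs_low"] = (risk == "high").astype(float)
        elif records[cov].dtype == object:
            levels = sorted(records[cov].unique())
            if len(levels) != 2:
                raise DataError(f"covariate {cov!r} must be binary, "
                                f"levels {levels}")
            if set(levels) == {"high", "low"}:  # score strata: high vs low
                one = "high"
            else:
                one = levels[1]
            X[cov] = (records[cov] == one).astype(float)
            ref = [l for l in levels if l != one][0]
            log.info("cox: coding %s as %s=1 vs %s=0", cov, one, ref)
        else:
            X[cov] = records[cov].astype(float)
    return X


def cox_multivariate(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit.

    Returns one row per design column with hazard ratio, Wald 95% CI and p.
    Constant covariates are a hard error; a fit with fewer than
    (#covariates + 5) events logs a warning.  Efron tie handling.
    """
    _check_records(records)
    X = _design_matrix(records, covariates)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise DataError(f"constant covariates: {const}")
    n_events = int(records["os_event"].sum())
    if n_events < X.shape[1] + 5:
        log.warning("cox: only %d events for %d covariates", n_events, X.shape[1])
    df = X.copy()
    df["os_time"] = records["os_time"].to_numpy()
    df["os_event"] = records["os_event"].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_time", event_col="os_event")
    except Exception as exc:
        raise DataError(f"Cox fit failed (separation/non-convergence?): {exc}") from exc
    s = cph.summary
    out = pd.DataFrame({
        "covariate": s.index,
        "coef": s["coef"].to_numpy(),
        "HR": s["exp(coef)"].to_numpy(),
        "HR_lower_95": s["exp(coef) lower 95%"].to_numpy(),
        "HR_upper_95": s["exp(coef) upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    return out


def gene_survival_correlation(expr: pd.DataFrame, records: pd.DataFrame,
                              per_gene_log2fc: pd.Series) -> dict:
    """Correlate per-gene differential expression with survival association.

    For each gene, a univariate Cox fit of standardized expression gives the
    log-hazard coefficient (positive = higher expression, worse survival);
    the Pearson correlation of these coefficients with the per-gene log2
    expression differences (LSC - Blast) is returned with its t-based p.
    """
    _check_records(records)
    genes = [g for g in per_gene_log2fc.index if g in expr.index]
    if len(genes) < 3:
        raise DataError(f"need >= 3 genes, found {len(genes)}")
    ids = records["sample_id"].tolist()
    missing = set(ids) - set(expr.columns)
    if missing:
        raise DataError(f"cohort samples absent from expression: {sorted(missing)[:5]}")
    coefs = []
    base = pd.DataFrame({
        "os_time": records["os_time"].to_numpy(),
        "os_event": records["os_event"].to_numpy(),
    })
    for g in genes:
        x = expr.loc[g, ids].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            coefs.append(np.nan)
            continue
        df = base.copy()
        df["x"] = (x - x.mean()) / sd
        cph = CoxPHFitter()
        cph.fit(df, duration_col="os_time", event_col="os_event")
        coefs.append(float(cph.summary.loc["x", "coef"]))
    frame = pd.DataFrame({"gene": genes, "cox_coef": coefs,
                          "log2fc": per_gene_log2fc.loc[genes].to_numpy()})
    frame = frame.dropna()
    r, p = stats.pearsonr(frame["log2fc"], frame["cox_coef"])
    return {"r": float(r), "p": float(p), "n_genes": len(frame), "table": frame}
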