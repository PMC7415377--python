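"""Multinomial-regression differentials of ASVs against culture covariates.

Each sample's count vector is modelled as Multinomial(n_i, softmax(z_i B))
with z_i the sample's design row (intercept + standardized covariates) and
B a coefficient matrix in additive-log-ratio (ALR) parameterization (the
last ASV is the fitting reference).  The penalized likelihood (independent
Normal prior of scale ``prior_sd`` on all non-intercept coefficients) is
maximized by batch quasi-Newton ascent, which is deterministic at this data
scale.  Reported differentials are the CLR-centered transform of the full
coefficient matrix, so they are reference-free: per covariate they sum to
zero across ASVs and express relative (not absolute) log-fold association.

ASVs whose differential lies more than three standard deviations from the
per-covariate mean (z-score rule) — or outside median +/- 1.5 IQR under the
box-whisker rule — are flagged as significantly associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .io_tables import FeatureTable, TaxonomyMap, UNASSIGNED, logger

#: The study's nominal covariate profile (metadata column -> display name).
DEFAULT_COVARIATES = {
    "bac_treated": "BAC",
    "dai": "DAI",
    "afdw_g_per_l": "AFDW",
    "do_mg_per_l": "DO",
    "biomass_prod": "biomass_prod",
    "water_temp_c": "temperature",
    "precip_mm": "precipitation",
    "solar_w_per_m2": "solar_radiation",
    "wind_m_per_s": "wind_speed",
}


@dataclass
class DesignMatrix:
    """Samples x (intercept + covariates), continuous columns standardized."""

    matrix: np.ndarray                   # (N, p+1), first column = 1
    covariates: list[str]                # names of the p non-intercept columns
    sample_ids: list[str]
    standardization: dict[str, tuple[float, float]]  # name -> (mean, sd)
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return ["Intercept"] + self.covariates


def build_design_matrix(metadata: pd.DataFrame, covariates,
                        sample_id_col: str = "sample_id") -> DesignMatrix:
    """Assemble a standardized design matrix from sample metadata.

    Binary/boolean covariates are coded 0/1 and left unscaled; continuous
    ones are z-scored (mean/sd recorded for invertibility).  Samples with
    any missing covariate are dropped with a logged manifest.
    """
    covariates = list(covariates)
    md = metadata.set_index(sample_id_col) if sample_id_col in metadata.columns else metadata
    missing_cols = [c for c in covariates if c not in md.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks covariate columns: {missing_cols}")
    sub = md[covariates].copy()
    keep = sub.notna().all(axis=1)
    dropped = list(sub.index[~keep].astype(str))
    if dropped:
        logger.warning("design matrix: dropped %d sample(s) with missing covariates: %s",
                       len(dropped), dropped)
    sub = sub.loc[keep]
    cols, standardization = [], {}
    for name in covariates:
        col = sub[name]
        if col.dtype == bool or set(pd.unique(col.dropna())) <= {0, 1, True, False}:
            cols.append(col.astype(float).to_numpy())
        else:
            mu, sd = float(col.mean()), float(col.std(ddof=0))
            if sd == 0:
                raise ValueError(f"covariate {name!r} is constant")
            standardization[name] = (mu, sd)
            cols.append(((col - mu) / sd).to_numpy())
    Z = np.column_stack([np.ones(len(sub))] + cols)
    return DesignMatrix(Z, covariates, list(sub.index.astype(str)),
                        standardization, dropped)


@dataclass
class DifferentialTable:
    """CLR-centered differentials with z-scores and fit diagnostics."""

    differentials: pd.DataFrame   # ASV x (Intercept + covariates)
    zscores: pd.DataFrame         # same shape, per-covariate standardized
    log_posterior: float
    n_iter: int
    converged: bool
    seed: int

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.differentials.columns if c != "Intercept"]


def fit_multinomial_differentials(table: FeatureTable, design: DesignMatrix,
                                  prior_sd: float = 1.0, seed: int = 0,
                                  max_iter: int = 2000, tol: float = 1e-9
                                  ) -> DifferentialTable:
    """Fit the penalized multinomial regression and report CLR differentials."""
    if list(table.sample_ids) != list(design.sample_ids):
        if set(table.sample_ids) >= set(design.sample_ids):
            table = table.filter_samples(design.sample_ids)
        else:
            raise ValueError("feature table and design matrix sample sets differ")
    X = table.counts.astype(float)
    Z = design.matrix
    N, D = X.shape
    P = Z.shape[1]
    if D < 2:
        raise ValueError("need at least two ASVs")
    n_i = X.sum(axis=1)
    # Normal penalty on non-intercept rows only: the intercept-only fit then
    # reproduces the closed-form CLR of the pooled composition.
    penalty_mask = np.ones((P, 1))
    penalty_mask[0, 0] = 0.0

    def objective(b_flat: np.ndarray) -> tuple[float, np.ndarray]:
        B = b_flat.reshape(P, D - 1)
        eta = np.concatenate([Z @ B, np.zeros((N, 1))], axis=1)
        log_norm = logsumexp(eta, axis=1)
        loglik = float((X * eta).sum() - n_i @ log_norm)
        pen = 0.5 * float((penalty_mask * B ** 2).sum()) / prior_sd ** 2
        p = np.exp(eta - log_norm[:, None])
        grad = Z.T @ (X[:, :-1] - n_i[:, None] * p[:, :-1])
        grad -= penalty_mask * B / prior_sd ** 2
        return -(loglik - pen), -grad.ravel()

    rng = np.random.default_rng(seed)
    b0 = rng.normal(scale=1e-6, size=P * (D - 1))
    res = minimize(objective, b0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9})
    if not res.success:
        logger.warning("multinomial differential fit did not fully converge: %s",
                       res.message)
    B = res.x.reshape(P, D - 1)
    full = np.concatenate([B, np.zeros((P, 1))], axis=1)   # ALR -> append ref
    clr = full - full.mean(axis=1, keepdims=True)          # center per covariate
    diffs = pd.DataFrame(clr.T, index=table.asv_ids, columns=design.names)
    z = diffs.apply(lambda col: (col - col.mean()) / col.std(ddof=0)
                    if col.std(ddof=0) > 0 else col * 0.0)
    return DifferentialTable(diffs, z, -float(res.fun), int(res.nit),
                             bool(res.success), seed)


# ---------------------------------------------------------------------------
# Outlier flagging and taxonomic summaries
# ---------------------------------------------------------------------------

def flag_outliers(diffs: DifferentialTable, method: str = "zscore",
                  threshold: float | None = None) -> pd.DataFrame:
    """Boolean ASV x covariate flags of significant differentials.

    ``zscore`` flags |d - mean| / sd > threshold (default 3); ``iqr`` flags
    values outside [q1 - t*IQR, q3 + t*IQR] (default t = 1.5).
    """
    if method == "zscore":
        threshold = 3.0 if threshold is None else threshold
        flags = {}
        for cov in diffs.differentials.columns:
            col = diffs.differentials[cov]
            sd = col.std(ddof=0)
            if sd == 0:
                logger.warning("covariate %r: zero spread, no outliers", cov)
                flags[cov] = pd.Series(False, index=col.index)
            else:
                flags[cov] = (col - col.mean()).abs() / sd > threshold
        return pd.DataFrame(flags)
    if method == "iqr":
        threshold = 1.5 if threshold is None else threshold
        flags = {}
        for cov in diffs.differentials.columns:
            col = diffs.differentials[cov]
            q1, q3 = col.quantile(0.25), col.quantile(0.75)
            iqr = q3 - q1
            if iqr == 0:
                logger.warning("covariate %r: zero IQR, no outliers", cov)
                flags[cov] = pd.Series(False, index=col.index)
            else:
                flags[cov] = (col < q1 - threshold * iqr) | (col > q3 + threshold * iqr)
        return pd.DataFrame(flags)
    raise ValueError(f"unknown outlier method {method!r}")


def summarize_by_order(diffs: DifferentialTable, flags: pd.DataFrame,
                       tax: TaxonomyMap, covariate: str) -> pd.DataFrame:
    """Per-order counts of positive/negative flagged ASVs for a covariate."""
    flagged = flags.index[flags[covariate]]
    rows: dict[str, dict[str, int]] = {}
    for asv in flagged:
        order = tax.rank_label(asv, "order") or UNASSIGNED
        sign = "positive" if diffs.differentials.loc[asv, covariate] > 0 else "negative"
        rows.setdefault(order, {"positive": 0, "negative": 0})[sign] += 1
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["positive", "negative"]).fillna(0).astype(int)
    out.index.name = "order"
    return out.sort_index()
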