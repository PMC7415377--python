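"""Dirichlet-multinomial mixture (DMM) community typing.

Samples (rows of the feature table, raw counts) are modelled as draws from a
mixture of Dirichlet-multinomial components; each component is a community
state type.  Fitting is EM: responsibilities from the component DM
likelihoods, mixture weights from responsibility means, and each component's
Dirichlet parameter vector updated by quasi-Newton ascent in log-alpha
(positivity without constraints) under a weak Normal prior on log-alpha.

Model size (number of components k) is chosen by a Laplace approximation of
the negative log model evidence: the penalized log-likelihood at the
optimum, corrected by half the log-determinant of the Hessian in the
log-alpha parameterization (block rank-1 + diagonal per component, so the
determinant is cheap via the matrix determinant lemma) and a
0.5*(k-1)*ln N term for the mixture weights.  Lower is better.

Cluster assignments ordered by (run, day) are summarised into a day-to-day
transition count matrix for community-state trajectory analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, polygamma, psi
from sklearn.cluster import KMeans

from .io_tables import FeatureTable, logger

#: Scale of the Normal(0, sd) prior on log-alpha (weakly informative).
LOG_ALPHA_PRIOR_SD = 10.0


@dataclass
class DMMModel:
    k: int
    weights: np.ndarray             # (k,)
    alpha: np.ndarray               # (k, D)
    responsibilities: np.ndarray    # (N, k)
    log_likelihood: float           # observed-data mixture log-likelihood
    log_posterior: float            # log_likelihood + log prior on log-alpha
    neg_log_evidence: float         # Laplace-approximated, lower is better
    seed: int
    n_restarts: int
    converged: bool
    n_iter: int
    sample_ids: list = field(default_factory=list)
    objective_trace: list = field(default_factory=list)

    @property
    def assignments(self) -> np.ndarray:
        """Hard cluster label per sample (argmax responsibility)."""
        return np.argmax(self.responsibilities, axis=1)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial log-likelihood
# ---------------------------------------------------------------------------

def dm_log_likelihood(counts_row, alpha_row, include_coefficient: bool = True) -> float:
    """Log pmf of a Dirichlet-multinomial observation.

    ln P(x | alpha) = [ln n! - sum ln x_j!] + ln G(A) - ln G(n+A)
                      + sum_j [ln G(x_j + a_j) - ln G(a_j)],   A = sum a_j.

    The multinomial coefficient term is included by default so the pmf sums
    to one over outcomes; it cancels in responsibilities either way.
    """
    x = np.asarray(counts_row, dtype=float)
    a = np.asarray(alpha_row, dtype=float)
    if (a <= 0).any():
        raise ValueError("all Dirichlet parameters must be positive")
    if (x < 0).any() or np.any(np.abs(x - np.round(x)) > 0):
        raise ValueError("counts must be nonnegative integers")
    n, A = x.sum(), a.sum()
    ll = gammaln(A) - gammaln(n + A) + np.sum(gammaln(x + a) - gammaln(a))
    if include_coefficient:
        ll += gammaln(n + 1) - np.sum(gammaln(x + 1))
    return float(ll)


def _loglik_matrix(X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """(N, k) matrix of DM log pmfs including the multinomial coefficient."""
    n = X.sum(axis=1)                                  # (N,)
    A = alphas.sum(axis=1)                             # (k,)
    core = gammaln(X[:, None, :] + alphas[None, :, :]).sum(axis=2)
    core -= gammaln(alphas).sum(axis=1)[None, :]
    core += gammaln(A)[None, :] - gammaln(n[:, None] + A[None, :])
    coef = gammaln(n + 1) - gammaln(X + 1).sum(axis=1)
    return core + coef[:, None]


# ---------------------------------------------------------------------------
# Weighted single-component fit in log-alpha (the EM M-step)
# ---------------------------------------------------------------------------

def _weighted_dm_objective(lam: np.ndarray, X: np.ndarray, r: np.ndarray,
                           prior_sd: float) -> tuple[float, np.ndarray]:
    """Negative penalized weighted DM log-likelihood and its gradient in lam."""
    a = np.exp(lam)
    A = a.sum()
    n = X.sum(axis=1)
    R = r.sum()
    ll = R * (gammaln(A) - gammaln(a).sum())
    ll -= r @ gammaln(n + A)
    ll += (r[:, None] * gammaln(X + a[None, :])).sum()
    # gradient wrt alpha
    g = (R * psi(A) - r @ psi(n + A)
         + (r[:, None] * psi(X + a[None, :])).sum(axis=0) - R * psi(a))
    # log prior and chain rule to lambda
    ll -= 0.5 * np.sum(lam ** 2) / prior_sd ** 2
    grad_lam = a * g - lam / prior_sd ** 2
    return -ll, -grad_lam


def _fit_component(X: np.ndarray, r: np.ndarray, lam0: np.ndarray,
                   prior_sd: float, maxiter: int = 40) -> np.ndarray:
    res = minimize(_weighted_dm_objective, lam0, args=(X, r, prior_sd),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12})
    # L-BFGS starting from the incumbent never worsens the objective
    f0, _ = _weighted_dm_objective(lam0, X, r, prior_sd)
    return res.x if res.fun <= f0 else lam0


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _clr_matrix(X: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    logp = np.log(X + pseudocount)
    logp -= np.log((X + pseudocount).sum(axis=1, keepdims=True))
    return logp - logp.mean(axis=1, keepdims=True)


def _init_responsibilities(X: np.ndarray, k: int, rstate: int) -> np.ndarray:
    N = X.shape[0]
    if k == 1:
        return np.ones((N, 1))
    km = KMeans(n_clusters=k, n_init=4, random_state=rstate)
    labels = km.fit_predict(_clr_matrix(X))
    resp = np.full((N, k), 1e-3)
    resp[np.arange(N), labels] = 1.0
    return resp / resp.sum(axis=1, keepdims=True)


def _mstep_alpha_init(X: np.ndarray, resp: np.ndarray, scale: float = 50.0) -> np.ndarray:
    rel = X / X.sum(axis=1, keepdims=True)
    k = resp.shape[1]
    alphas = np.empty((k, X.shape[1]))
    for c in range(k):
        w = resp[:, c]
        m = (w[:, None] * rel).sum(axis=0) / max(w.sum(), 1e-12)
        alphas[c] = np.maximum(m * scale, 1e-2)
    return alphas


def _penalized_objective(X: np.ndarray, weights: np.ndarray, alphas: np.ndarray,
                         prior_sd: float) -> tuple[float, float, np.ndarray]:
    """(log posterior, log likelihood, log responsibilities)."""
    ll_mat = _loglik_matrix(X, alphas)
    log_joint = np.log(weights)[None, :] + ll_mat
    log_norm = logsumexp(log_joint, axis=1)
    loglik = float(log_norm.sum())
    log_prior = -0.5 * float((np.log(alphas) ** 2).sum()) / prior_sd ** 2
    return loglik + log_prior, loglik, log_joint - log_norm[:, None]


def fit_dmm(table: FeatureTable | np.ndarray, k: int, seed: int = 0,
            n_restarts: int = 3, tol: float = 1e-6, max_iter: int = 500,
            prior_sd: float = LOG_ALPHA_PRIOR_SD) -> DMMModel:
    """Fit a k-component DMM by EM; best of ``n_restarts`` seeded starts."""
    if isinstance(table, FeatureTable):
        X = table.counts.astype(float)
        sample_ids = table.sample_ids
    else:
        X = np.asarray(table, dtype=float)
        sample_ids = list(range(X.shape[0]))
    N, D = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if N < k:
        raise ValueError(f"need at least k={k} samples, got {N}")

    best: DMMModel | None = None
    for restart in range(max(1, n_restarts)):
        rstate = (seed * 7919 + restart * 104729) % (2 ** 31 - 1)
        model = _fit_once(X, k, rstate, tol, max_iter, prior_sd)
        if best is None or model.log_posterior > best.log_posterior:
            best = model
    best.seed = seed
    best.n_restarts = n_restarts
    best.sample_ids = sample_ids
    best.neg_log_evidence = laplace_neg_log_evidence(X, best, prior_sd)
    if not best.converged:
        logger.warning("DMM EM (k=%d) did not converge in %d iterations", k, max_iter)
    return best


def _fit_once(X: np.ndarray, k: int, rstate: int, tol: float, max_iter: int,
              prior_sd: float) -> DMMModel:
    N = X.shape[0]
    resp = _init_responsibilities(X, k, rstate)
    alphas = _mstep_alpha_init(X, resp)
    weights = resp.mean(axis=0)
    obj, loglik, log_resp = _penalized_objective(X, weights, alphas, prior_sd)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resp = np.exp(log_resp)
        # M-step
        weights = np.maximum(resp.mean(axis=0), 1e-12)
        weights /= weights.sum()
        for c in range(k):
            lam0 = np.log(alphas[c])
            alphas[c] = np.exp(_fit_component(X, resp[:, c], lam0, prior_sd))
        new_obj, loglik, log_resp = _penalized_objective(X, weights, alphas, prior_sd)
        trace.append(new_obj)
        if abs(new_obj - obj) <= tol * (1.0 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    return DMMModel(k=k, weights=weights, alpha=alphas,
                    responsibilities=np.exp(log_resp), log_likelihood=loglik,
                    log_posterior=obj, neg_log_evidence=np.nan, seed=rstate,
                    n_restarts=1, converged=converged, n_iter=it,
                    objective_trace=trace)


# ---------------------------------------------------------------------------
# Laplace-approximated model evidence
# ---------------------------------------------------------------------------

def laplace_neg_log_evidence(X: np.ndarray, model: DMMModel,
                             prior_sd: float = LOG_ALPHA_PRIOR_SD) -> float:
    """Negative log model evidence via Laplace around the penalized optimum.

    -ln p(X | k) ~= -(L + ln prior) + 0.5 * sum_c ln det H_c
                    - (k D / 2) ln(2 pi) + 0.5 (k - 1) ln N
                    + k D ln(prior_sd sqrt(2 pi))

    where H_c is the negative Hessian in log-alpha of component c's
    responsibility-weighted penalized log-likelihood (rank-1 + diagonal:
    determinant by the matrix determinant lemma).  The last term is the
    prior normalising constant so evidences are comparable across k.
    """
    N, D = X.shape
    k = model.k
    total_logdet = 0.0
    for c in range(k):
        total_logdet += _component_logdet(X, model.responsibilities[:, c],
                                          model.alpha[c], prior_sd)
    log_prior = -0.5 * float((np.log(model.alpha) ** 2).sum()) / prior_sd ** 2
    log_prior -= k * D * np.log(prior_sd * np.sqrt(2 * np.pi))
    log_evidence = (model.log_likelihood + log_prior
                    + 0.5 * k * D * np.log(2 * np.pi) - 0.5 * total_logdet
                    - 0.5 * (k - 1) * np.log(N))
    return float(-log_evidence)


def _component_logdet(X: np.ndarray, r: np.ndarray, alpha: np.ndarray,
                      prior_sd: float) -> float:
    """ln det of H_c = (1/sd^2) I - Hessian_lambda(weighted loglik)."""
    a = alpha
    A = a.sum()
    n = X.sum(axis=1)
    R = r.sum()
    trigamma = lambda z: polygamma(1, z)
    # d2/dalpha: c * a a^T (shared) + diag(s); chain rule to lambda adds a*g
    c_shared = R * trigamma(A) - r @ trigamma(n + A)
    s = (r[:, None] * trigamma(X + a[None, :])).sum(axis=0) - R * trigamma(a)
    g = (R * psi(A) - r @ psi(n + A)
         + (r[:, None] * psi(X + a[None, :])).sum(axis=0) - R * psi(a))
    diag_h = 1.0 / prior_sd ** 2 - (a ** 2 * s + a * g)
    # H = diag_h - c_shared * (a a^T); guard against loss of positive
    # definiteness far from an interior optimum with a ridge.
    ridge = 0.0
    for _ in range(60):
        dh = diag_h + ridge
        if (dh > 0).all():
            lemma = 1.0 - c_shared * float((a ** 2 / dh).sum())
            if lemma > 0:
                return float(np.log(dh).sum() + np.log(lemma))
        ridge = max(ridge * 2.0, 1e-8)
    logger.warning("singular Laplace Hessian block; ridge-regularized determinant")
    dh = np.maximum(diag_h + ridge, 1e-8)
    return float(np.log(dh).sum())


def select_k(table: FeatureTable | np.ndarray, k_range, seed: int = 0,
             n_restarts: int = 3, tol: float = 1e-6, max_iter: int = 500,
             prior_sd: float = LOG_ALPHA_PRIOR_SD) -> tuple[int, list[float], list[DMMModel]]:
    """Fit every k in ``k_range``; best_k minimises the Laplace value.

    Returns (best_k, neg_log_evidence per k, fitted models per k).
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    models = [fit_dmm(table, k, seed=seed, n_restarts=n_restarts, tol=tol,
                      max_iter=max_iter, prior_sd=prior_sd) for k in ks]
    evidences = [m.neg_log_evidence for m in models]
    best_k = ks[int(np.argmin(evidences))]
    return best_k, evidences, models


# ---------------------------------------------------------------------------
# Transition matrix
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    counts: np.ndarray      # (k, k) integer transition counts
    labels: list            # cluster labels indexing rows/columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"from": self.labels[i], "to": self.labels[j], "count": int(self.counts[i, j])}
            for i in range(len(self.labels)) for j in range(len(self.labels))
            if self.counts[i, j] > 0
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count"])


def transitions(assignments: pd.DataFrame, k: int | None = None,
                pairing: str = "all_pairs") -> TransitionMatrix:
    """Count day-to-day cluster transitions within each run.

    ``assignments`` needs columns run_id, day, cluster.  Between consecutive
    observed days of a run, ``all_pairs`` pairing counts one transition per
    (sample on day t) x (sample on next day) pair; ``modal`` pairing reduces
    each day to its modal label first, contributing a single transition.
    """
    if pairing not in ("all_pairs", "modal"):
        raise ValueError(f"unknown pairing rule {pairing!r}")
    clusters = sorted(assignments["cluster"].unique())
    if k is not None:
        labels = list(range(k))
    else:
        labels = clusters
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for _, run in assignments.groupby("run_id"):
        days = sorted(run["day"].unique())
        for d_prev, d_next in zip(days[:-1], days[1:]):
            prev = run.loc[run["day"] == d_prev, "cluster"].tolist()
            nxt = run.loc[run["day"] == d_next, "cluster"].tolist()
            if pairing == "modal":
                prev = [pd.Series(prev).mode().iloc[0]]
                nxt = [pd.Series(nxt).mode().iloc[0]]
            for a in prev:
                for b in nxt:
                    counts[index[a], index[b]] += 1
    return TransitionMatrix(counts=counts, labels=labels)
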