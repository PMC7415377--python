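"""Alpha/beta diversity, ordination, group tests and log-ratio analyses.

Standard community-ecology machinery behind one surface: Faith's
phylogenetic diversity, Jaccard / Bray-Curtis / UniFrac distance matrices,
principal coordinates analysis, PERMANOVA and group dispersion (all via
scikit-bio), plus the compositional tests the pipeline interprets:
ANCOM's pairwise log-ratio W statistic and Pearson correlations between
summed-count log ratios and culture variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io_tables import FeatureTable, logger

PRESENCE_METRICS = ("jaccard", "unweighted_unifrac")
SUPPORTED_METRICS = ("jaccard", "braycurtis", "unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def faith_pd(sample_presence, tree: TreeNode) -> float:
    """Total branch length of the minimal rooted subtree over present tips.

    ``sample_presence`` is an iterable of ASV ids with nonzero counts.
    Empty samples have PD 0 by convention.
    """
    present = sorted(set(sample_presence))
    if not present:
        return 0.0
    tips = {t.name for t in tree.tips()}
    missing = [p for p in present if p not in tips]
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")
    return float(_skbio_faith_pd(np.ones(len(present)), present, tree))


def faith_pd_series(table: FeatureTable, tree: TreeNode) -> pd.Series:
    """Faith's PD per sample (presence = count > 0)."""
    values = {
        sid: faith_pd(
            [a for a, c in zip(table.asv_ids, row) if c > 0], tree)
        for sid, row in zip(table.sample_ids, table.counts)
    }
    return pd.Series(values, name="faith_pd")


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> FeatureTable:
    """Subsample each sample without replacement to a common depth."""
    depth = int(table.counts.sum(axis=1).min()) if depth is None else int(depth)
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    for i, row in enumerate(table.counts):
        if row.sum() < depth:
            raise ValueError(
                f"sample {table.sample_ids[i]!r} has fewer than {depth} counts")
        pool = np.repeat(np.arange(len(row)), row)
        chosen = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(chosen, minlength=len(row))
    return FeatureTable(pd.DataFrame(out, index=table.sample_ids,
                                     columns=table.asv_ids))


def pairwise_distances(table: FeatureTable, metric: str,
                       tree: TreeNode | None = None,
                       normalized: bool = False) -> DistanceMatrix:
    """All-pairs sample distances for one of the supported metrics.

    UniFrac metrics need a rooted tree covering every ASV.  Weighted UniFrac
    is the unnormalized variant by default (``normalized=True`` divides by
    the abundance-weighted tree depth).
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {SUPPORTED_METRICS}")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero samples make distances undefined")
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a phylogeny")
        kwargs = {"taxa": table.asv_ids, "tree": tree}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = normalized
        return beta_diversity(metric, table.counts, ids=table.sample_ids, **kwargs)
    if metric == "jaccard":
        return beta_diversity("jaccard", table.counts > 0, ids=table.sample_ids)
    return beta_diversity("braycurtis", table.counts, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # samples x retained positive axes
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # the dropped negative spectrum


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical PCoA (Gower centering + exact eigendecomposition).

    Axes with negative eigenvalues (non-Euclidean metrics) are reported and
    dropped; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    """
    res = _skbio_pcoa(dist, method="eigh", warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    neg = eig[eig < 0]
    pos_mask = eig > 0
    coords = res.samples.to_numpy()[:, pos_mask]
    coords = coords - coords.mean(axis=0, keepdims=True)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    frame = pd.DataFrame(coords, index=list(dist.ids), columns=cols)
    prop = res.proportion_explained.to_numpy()[pos_mask]
    return OrdinationResult(frame, eig, prop, neg)


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """Anderson's pseudo-F and permutation p-value, (1+b)/(1+m) estimator."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = list(groups)
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"groups with fewer than two samples: {small}")
    res = _skbio_permanova(dist, groups, permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def distance_to_centroid(dist: DistanceMatrix, groups,
                         reference_group) -> pd.Series:
    """Each sample's Euclidean distance to the reference group's centroid.

    Samples are embedded with :func:`pcoa` (positive axes only); the
    centroid is the coordinate mean of the reference group's samples.
    """
    groups = pd.Series(list(groups), index=list(dist.ids))
    ref_ids = groups.index[groups == reference_group]
    if len(ref_ids) == 0:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    coords = pcoa(dist).coordinates
    centroid = coords.loc[ref_ids].mean(axis=0)
    delta = coords - centroid
    return pd.Series(np.sqrt((delta ** 2).sum(axis=1)), name="distance_to_centroid")


# ---------------------------------------------------------------------------
# ANCOM
# ---------------------------------------------------------------------------

@dataclass
class AncomResult:
    w: pd.Series                 # per-ASV W statistic, 0..D-1
    detected: pd.Series          # boolean at the W-fraction cutoff
    cutoff: int
    alpha: float
    pseudocount: float
    test: str = "mannwhitney"


def ancom(table: FeatureTable, groups, pseudocount: float = 1.0,
          alpha: float = 0.05, w_cutoff_frac: float = 0.7) -> AncomResult:
    """Two-group ANCOM: W_i counts rejected pairwise log-ratio tests.

    For every ordered pair (i, j != i), a two-sample Mann-Whitney U test is
    run on log((x_i + pc) / (x_j + pc)); W_i is the number of rejections at
    ``alpha`` (no correction within pairs, per the canonical construction);
    ASV i is detected when W_i >= w_cutoff_frac * (D - 1).
    """
    groups = pd.Series(list(groups), index=table.sample_ids)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"ANCOM needs exactly two groups, got {levels}")
    sizes = groups.value_counts()
    if (sizes < 3).any():
        raise ValueError("each group needs at least three samples")
    D = table.n_asvs
    if D < 3:
        raise ValueError("need at least three ASVs")
    logx = np.log(table.counts + pseudocount)
    in_a = (groups == levels[0]).to_numpy()
    w = np.zeros(D, dtype=int)
    for i in range(D):
        ratios = logx[:, i][:, None] - logx  # (N, D) log ratios vs every j
        ratios = np.delete(ratios, i, axis=1)
        _, p = stats.mannwhitneyu(ratios[in_a], ratios[~in_a],
                                  alternative="two-sided", axis=0)
        w[i] = int((p < alpha).sum())
    cutoff = int(np.ceil(w_cutoff_frac * (D - 1)))
    w_series = pd.Series(w, index=table.asv_ids, name="W")
    return AncomResult(w_series, w_series >= cutoff, cutoff, alpha, pseudocount)


# ---------------------------------------------------------------------------
# Log-ratio correlations
# ---------------------------------------------------------------------------

@dataclass
class LogRatioCorrelation:
    r: float
    p_value: float
    slope: float
    intercept: float
    log_ratios: pd.Series


def logratio_correlation(table: FeatureTable, numerator, denominator,
                         variable, pseudocount: float = 0.5) -> LogRatioCorrelation:
    """Pearson correlation of a summed-count log ratio with a variable.

    Per sample: ln((sum of numerator counts + pc) / (sum of denominator
    counts + pc)); tested against ``variable`` (aligned to sample order)
    with a two-sided Pearson test and summarised by the least-squares line.
    """
    num = [a for a in numerator]
    den = [a for a in denominator]
    if not num or not den:
        raise ValueError("numerator and denominator sets must be nonempty")
    if set(num) & set(den):
        raise ValueError("numerator and denominator sets must be disjoint")
    unknown = [a for a in num + den if a not in table.data.columns]
    if unknown:
        raise ValueError(f"taxa absent from the table: {unknown}")
    y = np.log((table.data[num].sum(axis=1) + pseudocount)
               / (table.data[den].sum(axis=1) + pseudocount))
    x = np.asarray(variable, dtype=float)
    if len(x) != len(y):
        raise ValueError("variable length does not match sample count")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y.to_numpy())
    fit = stats.linregress(x, y.to_numpy())
    return LogRatioCorrelation(float(r), float(p), float(fit.slope),
                               float(fit.intercept),
                               pd.Series(y, index=table.sample_ids, name="log_ratio"))
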