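"""Readers, writers and validators for the pipeline's tabular inputs.

The pipeline consumes four artefacts produced upstream of any statistics:
an ASV feature table (integer counts, samples x ASVs), a taxonomy map
(ASV -> ranked lineage), a rooted phylogeny over the ASVs (newick), and a
sample-metadata time series per reactor run.  Everything here is plumbing:
parse, validate, normalise orientation/dialect, and apply the organelle
filter that restricts analysis to bacteria associated with the cultures.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("phycohealth")

#: Supported taxonomic ranks, outermost first.  Lineages may be truncated.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Label under which ASVs unclassified at the requested rank are grouped.
UNASSIGNED = "Unassigned"

#: Rank labels that mark an ASV as organellar rather than free-living bacterial.
ORGANELLE_LABELS = frozenset({"chloroplast", "mitochondria"})

#: Required columns of the sample-metadata TSV.
METADATA_COLUMNS = (
    "sample_id", "run_id", "reactor_id", "datetime", "dai", "afdw_g_per_l",
    "do_mg_per_l", "ph", "water_temp_c", "solar_w_per_m2", "wind_m_per_s",
    "precip_mm", "bac_treated",
)


class ValidationError(ValueError):
    """Malformed input: the message names the offending record."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

class FeatureTable:
    """Samples x ASVs matrix of nonnegative integer counts.

    Wraps a :class:`pandas.DataFrame` (index = sample ids, columns = ASV ids).
    Validation enforces unique ids, integer nonnegative counts, and drops
    samples whose total count is zero (recorded in ``dropped_samples``).
    """

    def __init__(self, data: pd.DataFrame, *, _validated: bool = False):
        if not _validated:
            data, dropped = _validate_counts(data)
            self.dropped_samples: list[str] = dropped
        else:
            self.dropped_samples = []
        self.data = data

    # -- accessors ----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable({self.n_samples} samples x {self.n_asvs} ASVs)"

    def filter_samples(self, keep: Sequence[str]) -> "FeatureTable":
        missing = [s for s in keep if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return FeatureTable(self.data.loc[list(keep)])

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample totals (rows sum to 1)."""
        return self.data.div(self.data.sum(axis=1), axis=0)


def _validate_counts(data: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    if data.index.has_duplicates:
        dupes = data.index[data.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    if data.columns.has_duplicates:
        dupes = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate ASV ids: {dupes}")
    values = data.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValidationError("feature table contains non-numeric cells")
    if values.size:
        bad = np.argwhere(~np.isfinite(values.astype(float)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-finite count at sample {data.index[i]!r}, ASV {data.columns[j]!r}")
        frac = values.astype(float) - np.round(values.astype(float))
        bad = np.argwhere(np.abs(frac) > 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-integer count at sample {data.index[i]!r}, ASV {data.columns[j]!r}")
        bad = np.argwhere(values < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"negative count at sample {data.index[i]!r}, ASV {data.columns[j]!r}")
    data = data.astype(np.int64)
    totals = data.sum(axis=1)
    dropped = list(data.index[totals == 0])
    if dropped:
        logger.warning("dropping %d zero-total sample(s): %s", len(dropped), dropped)
        data = data.loc[totals > 0]
    return data, dropped


def read_feature_table(path, orientation: str = "samples-as-rows") -> FeatureTable:
    """Read a TSV count table and normalise to samples x ASVs.

    ``orientation`` is ``"samples-as-rows"`` (default) or ``"asvs-as-rows"``
    (the transpose, as exported by some QIIME workflows).
    """
    if orientation not in ("samples-as-rows", "asvs-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    for col in raw.columns:
        try:
            raw[col] = pd.to_numeric(raw[col])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric values in column {col!r}: {exc}") from exc
    if orientation == "asvs-as-rows":
        raw = raw.T
    return FeatureTable(raw)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# TaxonomyMap
# ---------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")


@dataclass
class TaxonomyMap:
    """ASV -> ordered lineage ranks, with optional classifier confidence.

    Lineages are stored as tuples of rank labels outermost-first, with the
    ``x__`` prefixes stripped and empty trailing ranks removed.  ASVs absent
    from the map are treated as unclassified at every rank.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)
    confidence: dict[str, float] = field(default_factory=dict)

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        return self.lineages.get(asv_id, ())

    def rank_label(self, asv_id: str, rank: str) -> str | None:
        """Label of ``asv_id`` at ``rank`` or None if unclassified there."""
        idx = RANKS.index(rank)
        lin = self.lineage(asv_id)
        if idx < len(lin) and lin[idx]:
            return lin[idx]
        return None

    def is_organelle(self, asv_id: str) -> bool:
        return any(r.strip().lower() in ORGANELLE_LABELS for r in self.lineage(asv_id))


def parse_lineage(taxon: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage, stripping QIIME/SILVA prefixes."""
    parts = [p.strip() for p in str(taxon).split(";")]
    cleaned = [_PREFIX_RE.sub("", p).strip() for p in parts]
    while cleaned and not cleaned[-1]:
        cleaned.pop()
    return tuple(cleaned)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a QIIME-style taxonomy TSV (Feature ID, Taxon[, Confidence])."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.strip().lower(): c for c in raw.columns}
    try:
        id_col = cols.get("feature id") or cols["feature_id"]
    except KeyError as exc:
        raise ValidationError("taxonomy file lacks a 'Feature ID' column") from exc
    tax_col = cols.get("taxon")
    if tax_col is None:
        raise ValidationError("taxonomy file lacks a 'Taxon' column")
    conf_col = cols.get("confidence")
    tm = TaxonomyMap()
    for _, row in raw.iterrows():
        asv = str(row[id_col])
        if asv in tm.lineages:
            raise ValidationError(f"duplicate taxonomy entry for ASV {asv!r}")
        tm.lineages[asv] = parse_lineage(row[tax_col])
        if conf_col is not None and pd.notna(row[conf_col]):
            c = float(row[conf_col])
            if not 0.0 <= c <= 1.0:
                raise ValidationError(f"confidence outside [0,1] for ASV {asv!r}: {c}")
            tm.confidence[asv] = c
    return tm


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = []
    for asv, lin in tax.lineages.items():
        prefixes = [r[0] + "__" for r in RANKS]
        taxon = "; ".join(p + l for p, l in zip(prefixes, lin))
        rows.append({"Feature ID": asv, "Taxon": taxon,
                     "Confidence": tax.confidence.get(asv, "")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read and validate a rooted newick phylogeny over ASV tips."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen: set = set()
        dupes = sorted({t for t in tips if t in seen or seen.add(t)})
        raise ValidationError(f"duplicate tip labels: {dupes}")
    for node in tree.traverse(include_self=False):
        bl = node.length
        if bl is None:
            node.length = 0.0
        elif not np.isfinite(bl) or bl < 0:
            raise ValidationError(
                f"invalid branch length {bl!r} on node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# CultureSeries / metadata
# ---------------------------------------------------------------------------

@dataclass
class CultureSeries:
    """Per-run time series of AFDW and environmental covariates.

    ``records`` holds one row per sample ordered by timestamp with the
    columns of :data:`METADATA_COLUMNS`.  ``env`` optionally carries a dense
    within-day environment profile (columns: time_day, solar_w_per_m2,
    water_temp_c) used by the growth simulator; when absent, callers fall
    back to interpolating the sample records.
    """

    run_id: str
    reactor_id: str
    records: pd.DataFrame
    env: pd.DataFrame | None = None

    def __post_init__(self):
        rec = self.records
        ts = pd.to_datetime(rec["datetime"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValidationError(
                f"run {self.run_id!r}: timestamps must be strictly increasing")
        if (rec["afdw_g_per_l"] < 0).any():
            bad = rec.loc[rec["afdw_g_per_l"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"run {self.run_id!r}: negative AFDW at {bad!r}")
        dai = rec["dai"].to_numpy()
        if (np.diff(dai) < 0).any():
            raise ValidationError(
                f"run {self.run_id!r}: days-after-inoculation must be non-decreasing")

    def __len__(self) -> int:
        return len(self.records)


def read_metadata(path) -> dict[str, CultureSeries]:
    """Read the sample-metadata TSV into one CultureSeries per run."""
    raw = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"metadata lacks required columns: {missing}")
    raw["datetime"] = pd.to_datetime(raw["datetime"])
    raw["bac_treated"] = raw["bac_treated"].astype(bool)
    out = {}
    for run_id, grp in raw.groupby("run_id", sort=False):
        grp = grp.sort_values("datetime").reset_index(drop=True)
        reactor = str(grp["reactor_id"].iloc[0])
        out[str(run_id)] = CultureSeries(str(run_id), reactor, grp)
    return out


def write_metadata(series: Iterable[CultureSeries] | Mapping[str, CultureSeries], path) -> None:
    if isinstance(series, Mapping):
        series = series.values()
    frames = [s.records for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Organelle filter & taxonomic collapse
# ---------------------------------------------------------------------------

def filter_organelles(table: FeatureTable, tax: TaxonomyMap) -> FeatureTable:
    """Remove chloroplast/mitochondria ASVs, keeping survivor counts intact.

    ASVs with no taxonomy entry are retained (counted in the log).  Samples
    whose totals fall to zero after filtering are dropped with a warning.
    """
    keep, removed, unknown = [], [], 0
    for asv in table.asv_ids:
        if asv not in tax.lineages:
            unknown += 1
            keep.append(asv)
        elif tax.is_organelle(asv):
            removed.append(asv)
        else:
            keep.append(asv)
    if unknown:
        logger.info("organelle filter: %d ASV(s) without taxonomy retained", unknown)
    logger.info("organelle filter: removed %d of %d ASVs", len(removed), table.n_asvs)
    return FeatureTable(table.data[keep])


def collapse_taxonomy(table: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum counts over ASVs sharing the lineage label at ``rank``.

    ASVs unclassified at ``rank`` collapse into :data:`UNASSIGNED`.  Per-sample
    totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}; choose from {RANKS}")
    labels = [tax.rank_label(asv, rank) or UNASSIGNED for asv in table.asv_ids]
    collapsed = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return FeatureTable(collapsed)
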