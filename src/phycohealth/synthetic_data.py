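"""Synthetic reactor datasets with known planted structure.

Emulates the study design the pipeline targets: replicated baseline batch
runs sampled twice daily plus survey runs sampled every other day, with
AFDW trajectories produced by the healthy-growth simulator (optionally
crashed by a pathogen from a scheduled day, delayed in the biocide-treated
arm), and 16S count tables drawn from Dirichlet-multinomial mixtures whose
component schedule follows culture age, tilted log-linearly by covariates,
with a pathogen taxon rising during crashes and a planted fraction of
organelle ASVs.  Every generator is a pure function of (scenario, seed):
the emitted truth manifest suffices to regenerate all fixtures.

Lower-level generators (:func:`generate_mixture_counts`,
:func:`generate_differential_counts`) expose the planted-truth count
sampling directly for recovery benchmarking of the model-fitting stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .growth_model import EnvironmentSeries, GrowthModelParams, simulate_day
from .io_tables import CultureSeries, FeatureTable, TaxonomyMap

#: Order/genus label pools cycled over the non-pathogen taxa.
ORDER_POOL = (
    ("Rhizobiales", "Allorhizobium"), ("Betaproteobacteriales", "Hydrogenophaga"),
    ("Chitinophagales", "Sediminibacterium"), ("Bacillales", "Bacillus"),
    ("Pseudomonadales", "Pseudomonas"), ("Flavobacteriales", "Flavobacterium"),
    ("Sphingobacteriales", "Pedobacter"), ("Rhodobacterales", "Rhodobacter"),
    ("Burkholderiales", "Massilia"), ("Chromatiales", "Rheinheimera"),
)
PATHOGEN_LINEAGE = ("Bacteria", "Cyanobacteria", "Melainabacteria",
                    "Vampirovibrionales", "Vampirovibrionaceae", "Vampirovibrio")
CHLOROPLAST_LINEAGE = ("Bacteria", "Cyanobacteria", "Oxyphotobacteria", "Chloroplast")
MITOCHONDRIA_LINEAGE = ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                        "Rickettsiales", "Mitochondria")

MORNING_FRAC = 8.0 / 24.0
EVENING_FRAC = 18.0 / 24.0


@dataclass
class SyntheticScenario:
    """All knobs of the generator; defaults mirror the emulated study shape."""

    seed: int = 0
    # reactor layout
    n_baseline_runs: int = 4
    baseline_days: int = 14
    samples_per_day: int = 2          # morning + evening
    n_survey_runs: int = 8
    survey_days: int = 14
    survey_interval: int = 2          # sampled every other day
    # community
    n_taxa: int = 150
    depth_mean: float = 20000.0
    depth_log_sd: float = 0.25
    k_true: int = 3
    component_support: int = 10
    support_growth: int = 20          # extra taxa per later component (drives diversity)
    alpha_dominant: float = 8.0
    alpha_background: float = 0.02
    pathogen_index: int = 0
    pathogen_boost: float = 3.0       # per-crash-day multiplier on pathogen alpha
    organelle_fraction: float = 0.05
    # planted covariate effects (CLR scale per standardized covariate unit)
    effect_covariates: tuple = ("dai",)
    effect_sd: float = 0.8
    # culture dynamics
    growth_params: GrowthModelParams = field(default_factory=GrowthModelParams)
    afdw0: float = 0.05               # g/l at inoculation
    afdw_noise_sd: float = 0.05       # lognormal sd on evening AFDW
    crash_day: int = 7
    bac_crash_delay: int = 3
    crash_mu_factor: float = 0.5      # post-crash mu_obs = factor * mu_model
    env_step: float = 0.02            # day, environment sampling resolution
    t_mean: float = 28.0              # deg C seasonal mean water temperature
    t_amp: float = 5.0                # diurnal amplitude
    i_peak_mean: float = 900.0        # W m^-2 clear-sky midday irradiance

    def component_of_day(self, day: int, n_days: int) -> int:
        """Day -> planted community state (monotone schedule over the run)."""
        return min(int(self.k_true * day / max(n_days, 1)), self.k_true - 1)

    def run_ids(self) -> list[str]:
        base = [f"B{i + 1:02d}" for i in range(self.n_baseline_runs)]
        survey = [f"S{i + 1:02d}" for i in range(self.n_survey_runs)]
        return base + survey


def _rng(scenario_seed: int, *stream) -> np.random.Generator:
    """Deterministic keyed substream so each generator is independently pure."""
    return np.random.default_rng([int(scenario_seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# Environment and culture trajectories
# ---------------------------------------------------------------------------

def generate_environment(scenario: SyntheticScenario, run: int,
                         n_days: int | None = None
                         ) -> tuple[EnvironmentSeries, pd.DataFrame]:
    """Dense diurnal irradiance/temperature plus a per-day weather table.

    Irradiance is a half-sine between 06:00 and 18:00 with a seeded daily
    peak; temperature a sinusoid around the seasonal mean peaking
    mid-afternoon; wind lognormal and precipitation zero-inflated
    exponential, drawn per day.
    """
    rng = _rng(scenario.seed, 1, run)
    n_days = scenario.baseline_days if n_days is None else n_days
    times = np.arange(0.0, n_days, scenario.env_step)
    frac = times % 1.0
    day_idx = times.astype(int)
    i_peak = scenario.i_peak_mean * rng.uniform(0.7, 1.0, size=n_days)
    sun = np.sin(np.pi * np.clip((frac - 0.25) / 0.5, 0.0, 1.0))
    sun[(frac < 0.25) | (frac > 0.75)] = 0.0
    irradiance = i_peak[day_idx] * sun
    t_base = scenario.t_mean + rng.normal(0.0, 1.0, size=n_days)
    temp = t_base[day_idx] + scenario.t_amp * np.sin(2 * np.pi * (frac - 0.40))
    weather = pd.DataFrame({
        "day": np.arange(n_days),
        "wind_m_per_s": rng.lognormal(0.8, 0.5, size=n_days),
        "precip_mm": np.where(rng.random(n_days) < 0.1,
                              rng.exponential(4.0, size=n_days), 0.0),
        "i_peak": i_peak,
    })
    env = EnvironmentSeries(times, irradiance, temp)
    return env, weather


def generate_culture_run(scenario: SyntheticScenario, run: int,
                         run_id: str | None = None, bac_treated: bool = False,
                         n_days: int | None = None, sample_interval: int = 1,
                         crash: bool = True, noise: bool = True
                         ) -> tuple[CultureSeries, dict]:
    """AFDW trajectory simulated day-by-day with noise and optional crash.

    Returns the CultureSeries (records at sampled morning/evening times,
    dense environment attached) and a per-run truth dict (crash day,
    per-day growth factors).
    """
    rng = _rng(scenario.seed, 2, run)
    n_days = scenario.baseline_days if n_days is None else n_days
    env, weather = generate_environment(scenario, run, n_days=n_days)
    run_id = run_id or f"R{run:02d}"
    crash_day = scenario.crash_day + (scenario.bac_crash_delay if bac_treated else 0)
    params = scenario.growth_params
    rows = []
    afdw_m = scenario.afdw0
    t0 = pd.Timestamp("2017-06-01")
    for day in range(n_days):
        t_m = day + MORNING_FRAC
        t_e = day + EVENING_FRAC
        afdw_e_model, _ = simulate_day(afdw_m, env, params, t_m=t_m, t_e=t_e)
        afdw_e = afdw_e_model
        if crash and day >= crash_day:
            # pathogen halves realised growth in rate (not level) terms, so
            # the suppressed rate stays positive but below the model's
            afdw_e = afdw_m * (afdw_e_model / afdw_m) ** scenario.crash_mu_factor
        if noise and scenario.afdw_noise_sd > 0:
            afdw_e *= float(rng.lognormal(0.0, scenario.afdw_noise_sd))
        if day % sample_interval == 0:
            for t_day, afdw in ((t_m, afdw_m), (t_e, afdw_e)):
                i0, temp = env.interp(t_day)
                mu_day = np.log(afdw_e / afdw_m) / (t_e - t_m)
                w = weather.iloc[day]
                rows.append({
                    "sample_id": f"{run_id}.d{day:02d}.{'am' if t_day == t_m else 'pm'}",
                    "run_id": run_id,
                    "reactor_id": f"PW{run % 2 + 1}",
                    "datetime": t0 + pd.to_timedelta(t_day, unit="D"),
                    "dai": day,
                    "afdw_g_per_l": afdw,
                    "do_mg_per_l": float(np.clip(8.0 + 1.5 * mu_day
                                                 + rng.normal(0, 0.3), 0.0, None)),
                    "ph": float(8.0 + rng.normal(0, 0.1)),
                    "water_temp_c": temp,
                    "solar_w_per_m2": i0,
                    "wind_m_per_s": float(w["wind_m_per_s"]),
                    "precip_mm": float(w["precip_mm"]),
                    "bac_treated": bool(bac_treated),
                })
        afdw_m = afdw_e
    records = pd.DataFrame(rows)
    env_frame = pd.DataFrame({"time_day": env.times,
                              "solar_w_per_m2": env.irradiance,
                              "water_temp_c": env.water_temp})
    series = CultureSeries(run_id, rows[0]["reactor_id"], records, env=env_frame)
    truth = {"run_id": run_id, "crash_day": int(crash_day) if crash else None,
             "bac_treated": bool(bac_treated)}
    return series, truth


# ---------------------------------------------------------------------------
# Planted community components and count sampling
# ---------------------------------------------------------------------------

def make_separated_components(k: int, D: int, seed: int = 0,
                              support: int = 10, support_growth: int = 0,
                              alpha_dominant: float = 8.0,
                              alpha_background: float = 0.02,
                              skip: tuple = ()) -> np.ndarray:
    """k Dirichlet parameter rows with disjoint dominant taxon blocks.

    Component c gets ``support + c * support_growth`` dominant taxa (later
    components are richer, driving the diversity-with-age trend).  Indices
    in ``skip`` (e.g. the pathogen and organelles) never become dominants.
    """
    rng = _rng(seed, 3)
    alphas = np.full((k, D), alpha_background)
    available = [j for j in range(D) if j not in set(skip)]
    pos = 0
    for c in range(k):
        size = support + c * support_growth
        block = available[pos:pos + size]
        if len(block) < size:
            raise ValueError("not enough taxa for disjoint component supports")
        pos += size
        alphas[c, block] = alpha_dominant * rng.uniform(0.5, 1.5, size=size)
    return alphas


def generate_mixture_counts(alphas: np.ndarray, n: int, depth: float = 5000.0,
                            seed: int = 0, weights=None, labels=None,
                            depth_log_sd: float = 0.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Draw DM mixture counts; returns (counts, component labels)."""
    rng = _rng(seed, 4)
    k, D = np.asarray(alphas).shape
    if labels is None:
        weights = np.full(k, 1.0 / k) if weights is None else np.asarray(weights)
        labels = rng.choice(k, size=n, p=weights / weights.sum())
    else:
        labels = np.asarray(labels, dtype=int)
        if len(labels) != n:
            raise ValueError("labels length must equal n")
    counts = np.zeros((n, D), dtype=np.int64)
    for i, lab in enumerate(labels):
        p = rng.dirichlet(alphas[lab])
        d = int(np.round(depth * np.exp(rng.normal(0.0, depth_log_sd)))) if depth_log_sd else int(depth)
        counts[i] = rng.multinomial(max(d, 1), p)
    return counts, labels


def generate_differential_counts(n: int, D: int, depth: float = 10000.0,
                                 effect_covariates: tuple = ("effect",),
                                 null_covariates: tuple = ("null",),
                                 effect_sd: float = 0.8,
                                 dispersion_sd: float = 0.5,
                                 base_log_sd: float = 0.5,
                                 seed: int = 0
                                 ) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    """Counts with planted log-linear covariate effects.

    Covariate values are standard normal draws.  Per sample the composition
    is softmax(log base + z_i . beta + eps) with a lognormal base
    composition (log-sd ``base_log_sd``) and logistic-normal overdispersion
    eps ~ Normal(0, dispersion_sd) i.i.d. per taxon — the regression model's
    own noise family, so every taxon's planted coefficient is identifiable
    with the same log-scale noise.  Effect covariates get centered
    Normal(0, effect_sd) coefficient vectors, null covariates exactly zero.
    Returns (table, covariate frame, true CLR differentials as covariate x
    taxon frame).
    """
    rng = _rng(seed, 5)
    taxa = [f"ASV{j:03d}" for j in range(D)]
    samples = [f"S{i:03d}" for i in range(n)]
    log_base = rng.normal(0.0, base_log_sd, size=D)
    covs = list(effect_covariates) + list(null_covariates)
    Z = rng.normal(size=(n, len(covs)))
    B = np.zeros((len(covs), D))
    for idx, name in enumerate(covs):
        if name in effect_covariates:
            b = rng.normal(0.0, effect_sd, size=D)
            B[idx] = b - b.mean()
    counts = np.zeros((n, D), dtype=np.int64)
    for i in range(n):
        eta = log_base + Z[i] @ B + rng.normal(0.0, dispersion_sd, size=D)
        p = np.exp(eta - eta.max())
        p /= p.sum()
        counts[i] = rng.multinomial(int(depth), p)
    table = FeatureTable(pd.DataFrame(counts, index=samples, columns=taxa))
    cov_frame = pd.DataFrame(Z, index=samples, columns=covs)
    cov_frame.index.name = "sample_id"
    truth = pd.DataFrame(B, index=covs, columns=taxa)
    return table, cov_frame, truth


# ---------------------------------------------------------------------------
# Taxonomy and tree
# ---------------------------------------------------------------------------

def generate_taxonomy(scenario: SyntheticScenario, taxa: list[str],
                      organelle_ids: list[str]) -> TaxonomyMap:
    tm = TaxonomyMap()
    organelles = set(organelle_ids)
    pathogen = taxa[scenario.pathogen_index]
    mito_toggle = False
    for j, asv in enumerate(taxa):
        if asv == pathogen:
            tm.lineages[asv] = PATHOGEN_LINEAGE
        elif asv in organelles:
            tm.lineages[asv] = MITOCHONDRIA_LINEAGE if mito_toggle else CHLOROPLAST_LINEAGE
            mito_toggle = not mito_toggle
        else:
            order, genus = ORDER_POOL[j % len(ORDER_POOL)]
            tm.lineages[asv] = ("Bacteria", f"Phylum{j % 4 + 1}", f"Class{j % 6 + 1}",
                                order, f"{order}aceae", f"{genus}", f"{genus}_sp{j}")
        tm.confidence[asv] = 0.99
    return tm


def generate_tree(scenario: SyntheticScenario, taxa: list[str] | None = None) -> TreeNode:
    """Random rooted bifurcating tree by sequential join; exponential lengths."""
    rng = _rng(scenario.seed, 6)
    if taxa is None:
        taxa = [f"ASV{j:03d}" for j in range(scenario.n_taxa)]
    if len(taxa) < 2:
        raise ValueError("need at least two taxa for a tree")
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.1))) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.exponential(0.1)),
                          children=[nodes[i], nodes[j]])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    root = TreeNode(name="root", children=nodes, length=0.0)
    return root


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    table: FeatureTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    metadata: pd.DataFrame
    series: dict[str, CultureSeries]
    truth: dict


def generate_counts(scenario: SyntheticScenario, covariates: pd.DataFrame
                    ) -> tuple[FeatureTable, TaxonomyMap, dict]:
    """Count table for an assembled covariate table (one row per sample).

    ``covariates`` needs sample_id, run_id, dai, bac_treated plus any effect
    covariates; the day's scheduled component's Dirichlet row is tilted by
    the planted log-linear effects and the pathogen's crash loading, then
    composition ~ Dirichlet and counts ~ Multinomial(depth).
    """
    rng = _rng(scenario.seed, 7)
    D = scenario.n_taxa
    taxa = [f"ASV{j:03d}" for j in range(D)]
    n_org = int(round(scenario.organelle_fraction * D))
    organelle_ids = taxa[D - n_org:] if n_org else []
    org_idx = np.arange(D - n_org, D) if n_org else np.array([], dtype=int)
    skip = tuple(org_idx) + (scenario.pathogen_index,)
    alphas = make_separated_components(
        scenario.k_true, D, seed=scenario.seed,
        support=scenario.component_support, support_growth=scenario.support_growth,
        alpha_dominant=scenario.alpha_dominant,
        alpha_background=scenario.alpha_background, skip=skip)
    if n_org:
        # organelle carry-over: a constant few percent of every community
        alphas[:, org_idx] = (0.03 * alphas.sum(axis=1, keepdims=True) / n_org)

    # planted CLR effects per standardized covariate
    effects = {}
    for name in scenario.effect_covariates:
        name_key = sum(ord(ch) for ch in name)  # stable across processes
        b = _rng(scenario.seed, 8, name_key).normal(
            0.0, scenario.effect_sd, size=D)
        effects[name] = b - b.mean()

    crash_days = scenario.crash_day, scenario.crash_day + scenario.bac_crash_delay
    counts = np.zeros((len(covariates), D), dtype=np.int64)
    labels = np.zeros(len(covariates), dtype=int)
    run_days = {True: scenario.baseline_days, False: scenario.survey_days}
    for i, (_, row) in enumerate(covariates.iterrows()):
        n_days = run_days.get(str(row["run_id"]).startswith("B"), scenario.baseline_days)
        comp = scenario.component_of_day(int(row["dai"]), n_days)
        labels[i] = comp
        alpha_i = alphas[comp].copy()
        for name, b in effects.items():
            z = float(row[f"_z_{name}"])
            alpha_i = alpha_i * np.exp(z * b)
        crash_day = crash_days[1] if row["bac_treated"] else crash_days[0]
        over = int(row["dai"]) - crash_day
        if over >= 0:
            alpha_i[scenario.pathogen_index] = (
                alpha_i.sum() * 0.05 * scenario.pathogen_boost ** min(over, 4))
        depth = int(np.round(scenario.depth_mean
                             * np.exp(rng.normal(0.0, scenario.depth_log_sd))))
        p = rng.dirichlet(alpha_i)
        counts[i] = rng.multinomial(max(depth, 1), p)
    table = FeatureTable(pd.DataFrame(counts, index=list(covariates["sample_id"]),
                                      columns=taxa))
    tm = generate_taxonomy(scenario, taxa, organelle_ids)
    truth = {
        "component_labels": {s: int(l) for s, l in
                             zip(covariates["sample_id"], labels)},
        "component_alphas": alphas.tolist(),
        "clr_effects": {k: v.tolist() for k, v in effects.items()},
        "pathogen_id": taxa[scenario.pathogen_index],
        "organelle_ids": organelle_ids,
    }
    return table, tm, truth


def generate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """The full fixture bundle: runs, metadata, counts, taxonomy, tree, truth."""
    series: dict[str, CultureSeries] = {}
    run_truth = []
    frames = []
    run_ids = scenario.run_ids()
    for r, run_id in enumerate(run_ids):
        baseline = run_id.startswith("B")
        bac = (r % 2 == 0)  # alternate treatment arms
        cs, truth = generate_culture_run(
            scenario, r, run_id=run_id, bac_treated=bac,
            n_days=scenario.baseline_days if baseline else scenario.survey_days,
            sample_interval=1 if baseline else scenario.survey_interval)
        series[run_id] = cs
        run_truth.append(truth)
        frames.append(cs.records)
    metadata = pd.concat(frames, ignore_index=True)

    # standardized effect covariates for the planted log-linear tilts
    cov = metadata.copy()
    for name in scenario.effect_covariates:
        col = cov[name].astype(float)
        cov[f"_z_{name}"] = (col - col.mean()) / col.std(ddof=0)
    table, tm, truth = generate_counts(scenario, cov)
    tree = generate_tree(scenario, table.asv_ids)
    truth["runs"] = run_truth
    truth["scenario"] = _scenario_manifest(scenario)
    return SyntheticDataset(table, tm, tree, metadata, series, truth)


def _scenario_manifest(scenario: SyntheticScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["growth_params"] = dataclasses.asdict(scenario.growth_params)
    return d


def scenario_from_manifest(manifest: dict) -> SyntheticScenario:
    d = dict(manifest)
    d["growth_params"] = GrowthModelParams(**d["growth_params"])
    d["effect_covariates"] = tuple(d["effect_covariates"])
    return SyntheticScenario(**d)
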