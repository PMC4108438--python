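"""Synthetic camera-trap survey generator.

Emulates a single-season tropical-forest camera-trap campaign: a regular
grid of camera sites along an east-west disturbance/elevation gradient,
staggered deployment arrays, and a mammal community whose occupancy and
daily detection probabilities follow a hierarchical logit-normal model
(species-level random effects around community means, trophic-guild and
body-mass structure on detection).  Every downstream stage of the pipeline
can therefore be tested by parameter recovery against known truth.

The default parameter values mirror the design this pipeline targets:
60 sites at one camera per 2 km^2, three consecutive arrays of 20 cameras
run for ~30 days each, border distance strongly correlated with elevation
(r ~ 0.8), ~30 true species of which a handful go undetected, and daily
detection ordered herbivore > omnivore > insectivore ~ carnivore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for tests)

GUILDS = ("carnivore", "herbivore", "omnivore", "insectivore")

HABITAT_CLASSES = ("regenerating", "deciduous", "montane")


def _child_seed(seed: int | None, index: int) -> int:
    """Derive a deterministic 31-bit child seed from a master seed."""
    ss = np.random.SeedSequence(0 if seed is None else int(seed))
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeParams:
    """Site grid and covariate-field parameters.

    ``habitat_breakpoints`` are thresholds (metres) on distance to the
    eastern border: below the first the forest is regenerating, between
    the two it is deciduous, above the second montane — the lowland to
    montane east-west gradient.
    """

    n_sites: int = 60
    grid_spacing_m: float = 1414.0  # one camera per ~2 km^2
    border_elev_corr: float = 0.8
    habitat_breakpoints: tuple[float, float] = (2500.0, 5500.0)

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError(f"n_sites must be >= 2, got {self.n_sites}")
        if not abs(self.border_elev_corr) < 1:
            raise ValueError("|border_elev_corr| must be < 1")
        if self.grid_spacing_m <= 0:
            raise ValueError("grid_spacing_m must be positive")


def simulate_landscape(params: LandscapeParams, seed: int | None = None) -> pd.DataFrame:
    """Generate one row of site covariates per camera site.

    Sites sit on a near-square grid with small placement jitter (cameras
    are repositioned up to ~100 m in the field).  Distance to the eastern
    park border increases westward with the grid column; elevation is a
    linear function of border distance plus Gaussian noise calibrated so
    that the expected Pearson correlation equals ``border_elev_corr``.
    Habitat class is assigned by thresholding border distance.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_sites
    ncols = math.ceil(math.sqrt(n))
    idx = np.arange(n)
    col, row = idx % ncols, idx // ncols
    sp = params.grid_spacing_m
    x = col * sp + rng.uniform(-100, 100, n)
    y = row * sp + rng.uniform(-100, 100, n)

    border = x - x.min() + rng.uniform(200.0, 400.0, n)

    r = params.border_elev_corr
    slope_e = 0.18 * (1 if r >= 0 else -1)  # m elevation per m border distance
    if r == 0:
        elev = 900.0 + rng.normal(0.0, 300.0, n)
    else:
        sd_b = border.std(ddof=1)
        sd_noise = abs(slope_e) * sd_b * math.sqrt(1.0 / r**2 - 1.0)
        elev = 350.0 + slope_e * border + rng.normal(0.0, sd_noise, n)

    edge = rng.gamma(shape=2.0, scale=800.0, size=n)
    river = rng.gamma(shape=2.0, scale=500.0, size=n)
    slope = rng.uniform(0.0, 40.0, n)

    b1, b2 = params.habitat_breakpoints
    habitat = np.where(border < b1, "regenerating",
                       np.where(border < b2, "deciduous", "montane"))

    return pd.DataFrame({
        "site_id": [f"CT-{i + 1:03d}" for i in range(n)],
        "x": np.round(x, 1),
        "y": np.round(y, 1),
        "border_m": np.round(border, 1),
        "edge_m": np.round(edge, 1),
        "river_m": np.round(river, 1),
        "slope": np.round(slope, 2),
        "elevation_m": np.round(elev, 1),
        "habitat": habitat,
    })


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------

@dataclass
class CommunityParams:
    """Hierarchical community model parameters.

    Species draw a latent pair (u_k, v_k) from a bivariate normal with
    means (mu_u, mu_v), SDs (sigma_u, sigma_v) and correlation rho.
    u_k is the species' logit-occupancy intercept; v_k its logit *daily*
    detection intercept (detection of one animal passage per active
    camera-day at an occupied site).  ``beta_psi`` maps standardized site
    covariate names to community-wide effects on logit occupancy;
    ``alpha_p`` maps guild names, ``"log_mass"`` and standardized site
    covariate names to effects on logit daily detection (carnivore is the
    reference guild).

    The default detection structure makes herbivores by far the most
    detectable guild and carnivores the least, with a weak negative mass
    effect — daily logits chosen so that 5-day-occasion detection at an
    average species sits near 0.5 (herbivore) down to ~0.06 (carnivore).
    """

    n_species_true: int = 30
    guild_probs: dict[str, float] = field(default_factory=lambda: {
        "carnivore": 0.18, "herbivore": 0.22, "omnivore": 0.40, "insectivore": 0.20,
    })
    mass_log_mean: float = 1.0   # log kg: median body mass ~2.7 kg
    mass_log_sd: float = 1.3
    mu_u: float = -1.0           # community mean logit occupancy (~0.27)
    mu_v: float = -4.6           # daily detection logit, carnivore reference
    sigma_u: float = 1.5
    sigma_v: float = 1.0
    rho: float = 0.5
    beta_psi: dict[str, float] = field(default_factory=dict)
    alpha_p: dict[str, float] = field(default_factory=lambda: {
        "herbivore": 2.8, "omnivore": 1.5, "insectivore": 0.7, "log_mass": -0.10,
    })
    seed: int | None = None

    def validate(self) -> None:
        if self.n_species_true < 1:
            raise ValueError("n_species_true must be >= 1")
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("sigma_u and sigma_v must be non-negative")
        if not abs(self.rho) <= 1:
            raise ValueError("|rho| must be <= 1")
        probs = np.array([self.guild_probs.get(g, 0.0) for g in GUILDS])
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("guild_probs must be a simplex over the four guilds")


def simulate_community(params: CommunityParams, seed: int | None = None) -> pd.DataFrame:
    """Draw per-species traits and latent effects.

    Returns one row per species with guild, body mass (kg) and the latent
    bivariate-normal pair (u, v) on the logit scale.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_species_true
    probs = np.array([params.guild_probs.get(g, 0.0) for g in GUILDS])
    guild = rng.choice(GUILDS, size=n, p=probs)
    mass = np.exp(rng.normal(params.mass_log_mean, params.mass_log_sd, n))
    cov = params.rho * params.sigma_u * params.sigma_v
    sigma = np.array([[params.sigma_u**2, cov], [cov, params.sigma_v**2]])
    degenerate = (params.sigma_u == 0 or params.sigma_v == 0
                  or abs(params.rho) == 1)
    uv = rng.multivariate_normal([params.mu_u, params.mu_v], sigma, size=n,
                                 method="svd" if degenerate else "cholesky")
    return pd.DataFrame({
        "species": [f"sp{k + 1:02d}" for k in range(n)],
        "guild": guild,
        "mass_kg": np.round(mass, 3),
        "u": uv[:, 0],
        "v": uv[:, 1],
    })


def _zscore(a: np.ndarray) -> np.ndarray:
    if len(a) < 2:
        return np.zeros_like(a, dtype=float)
    sd = a.std(ddof=1)
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a, dtype=float)


def species_site_logits(
    species: pd.DataFrame,
    sites: pd.DataFrame,
    params: CommunityParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Logit occupancy and logit daily detection, species x sites.

    Covariate effects apply to internally z-scored site covariates;
    ``habitat`` as a covariate name means the montane-vs-lowland dummy.
    The guild and log-mass terms of ``alpha_p`` shift detection per
    species (carnivore reference; log mass z-scored across species).
    """
    n_k, n_i = len(species), len(sites)

    def site_vector(name: str) -> np.ndarray:
        if name == "habitat":
            return (sites["habitat"].to_numpy() == "montane").astype(float)
        col = name if name in sites.columns else f"{name}_m"
        return _zscore(sites[col].to_numpy(dtype=float))

    eta_psi = np.broadcast_to(species["u"].to_numpy()[:, None], (n_k, n_i)).copy()
    for name, beta in params.beta_psi.items():
        eta_psi += beta * site_vector(name)[None, :]

    eta_p = np.broadcast_to(species["v"].to_numpy()[:, None], (n_k, n_i)).copy()
    log_mass_z = _zscore(np.log(species["mass_kg"].to_numpy(dtype=float)))
    for name, alpha in params.alpha_p.items():
        if name in GUILDS:
            eta_p += alpha * (species["guild"].to_numpy() == name).astype(float)[:, None]
        elif name == "log_mass":
            eta_p += alpha * log_mass_z[:, None]
        else:
            eta_p += alpha * site_vector(name)[None, :]
    return eta_psi, eta_p


# ---------------------------------------------------------------------------
# Deployments and detection records
# ---------------------------------------------------------------------------

@dataclass
class DeploymentPlan:
    """Staggered deployment arrays.

    ``arrays`` is a list of (site-id list, start date) pairs; every site
    must appear in exactly one array.  ``failure_prob`` is the chance a
    camera malfunctions entirely and contributes no records or effort.
    """

    arrays: list[tuple[list[str], pd.Timestamp]]
    nominal_days: int = 30
    failure_prob: float = 0.0

    def validate(self) -> None:
        if not self.arrays:
            raise ValueError("deployment plan has no arrays")
        if self.nominal_days < 1:
            raise ValueError("nominal_days must be >= 1")
        if not 0 <= self.failure_prob <= 1:
            raise ValueError("failure_prob must be in [0, 1]")
        all_sites = [s for sites, _ in self.arrays for s in sites]
        if len(all_sites) != len(set(all_sites)):
            raise ValueError("a site appears in more than one array")

    @property
    def site_ids(self) -> list[str]:
        return [s for sites, _ in self.arrays for s in sites]


def default_deployment_plan(
    site_ids: list[str] | pd.Series,
    n_arrays: int = 3,
    nominal_days: int = 30,
    failure_prob: float = 2 / 60,
    first_start: str = "2009-07-24",
    stagger_days: int = 35,
) -> DeploymentPlan:
    """Split sites into consecutive arrays with staggered start dates."""
    ids = list(site_ids)
    start = pd.Timestamp(first_start)
    per = math.ceil(len(ids) / n_arrays)
    arrays = [
        (ids[a * per:(a + 1) * per], start + pd.Timedelta(days=a * stagger_days))
        for a in range(n_arrays)
        if ids[a * per:(a + 1) * per]
    ]
    return DeploymentPlan(arrays=arrays, nominal_days=nominal_days,
                          failure_prob=failure_prob)


def simulate_detections(
    species: pd.DataFrame,
    sites: pd.DataFrame,
    plan: DeploymentPlan,
    params: CommunityParams,
    seed: int | None = None,
    mean_extra_images: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate image records and the deployment table.

    Latent occupancy z_ik ~ Bernoulli(psi_ik) is drawn once per
    species-site and held fixed for the season (closure).  On each active
    camera-day at an occupied site, one passage event occurs with the
    species' daily detection probability; an event emits 1 + Poisson
    images clustered within less than an hour, so that collapsing image
    records back to events is non-trivial.  Malfunctioning cameras emit
    no records and are written with ``functioning = False`` and a
    zero-length deployment.

    Returns ``(records, deployments)``: records have columns
    (site_id, species, timestamp); deployments (site_id, start, end,
    functioning) with ``end`` exclusive, so effort days = end - start.
    """
    plan.validate()
    missing = set(sites["site_id"]) - set(plan.site_ids)
    if missing:
        raise ValueError(f"plan does not cover sites: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    site_index = {s: j for j, s in enumerate(sites["site_id"])}
    eta_psi, eta_p = species_site_logits(species, sites, params)
    psi, p_daily = expit(eta_psi), expit(eta_p)
    z = rng.random(psi.shape) < psi  # closure: drawn once per season

    dep_rows, rec_rows = [], []
    for site_list, start in plan.arrays:
        for sid in site_list:
            functioning = rng.random() >= plan.failure_prob
            n_days = plan.nominal_days if functioning else 0
            dep_rows.append({
                "site_id": sid,
                "start": start,
                "end": start + pd.Timedelta(days=n_days),
                "functioning": functioning,
            })
            if not functioning:
                continue
            i = site_index[sid]
            # daily Bernoulli passage per occupying species
            day_hits = rng.random((len(species), n_days)) < (p_daily[:, [i]] * z[:, [i]])
            for k, d in zip(*np.nonzero(day_hits)):
                # event start in [00:00, 22:00) keeps each image cluster
                # (< 60 min long) more than an hour from the next day's
                start_min = rng.integers(0, 22 * 60)
                n_images = int(min(1 + rng.poisson(mean_extra_images), 59))
                offsets = np.sort(rng.choice(np.arange(1, 60), size=n_images - 1,
                                             replace=False)) if n_images > 1 else []
                t0 = start + pd.Timedelta(days=int(d), minutes=int(start_min))
                times = [t0] + [t0 + pd.Timedelta(minutes=int(o)) for o in offsets]
                name = species["species"].iloc[k]
                rec_rows.extend({"site_id": sid, "species": name, "timestamp": t}
                                for t in times)

    deployments = pd.DataFrame(dep_rows)
    records = pd.DataFrame(rec_rows, columns=["site_id", "species", "timestamp"])
    if len(records):
        records = records.sort_values(["site_id", "species", "timestamp"],
                                      kind="mergesort").reset_index(drop=True)
    return records, deployments


def simulate_dataset(
    landscape: LandscapeParams | None = None,
    community: CommunityParams | None = None,
    plan: DeploymentPlan | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """One-call synthetic survey: covariates, traits, records, deployments.

    A master seed deterministically streams child seeds to the landscape,
    community and detection stages.
    """
    landscape = landscape or LandscapeParams()
    community = community or CommunityParams()
    sites = simulate_landscape(landscape, _child_seed(seed, 0))
    species = simulate_community(community, _child_seed(seed, 1))
    plan = plan or default_deployment_plan(sites["site_id"])
    records, deployments = simulate_detections(
        species, sites, plan, community, _child_seed(seed, 2))
    traits = species[["species", "guild", "mass_kg"]].rename(
        columns={"guild": "guild"})[["species", "mass_kg", "guild"]]
    return {
        "sites": sites,
        "species": species,
        "traits": traits,
        "records": records,
        "deployments": deployments,
    }
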