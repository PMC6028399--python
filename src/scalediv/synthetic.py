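"""Synthetic survey-data generators with known ground truth.

Emulates the structure of a roadside breeding-bird survey: routes with five
within-route segments acting as repeated samples, a latent occupancy state per
species x route, Bernoulli detection given presence, logit-linear occupancy in
(standardised) elevation, species-level coefficients drawn from community
hyperdistributions, optional per-species linear occupancy trends on the logit
scale, regionally blocked routes, trait tables with simplex-constrained diet
and foraging-niche axes, and a small global-extinction record.

Every generator is deterministic under its ``seed`` argument, and the latent
truth (coefficients and occupancy states) is retained so downstream estimators
can be tested against known values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import DEFAULT_PROJECTION, EqualAreaProjection

N_SEGMENTS = 5

DIET_AXES = [
    "diet_invertebrates",
    "diet_vertebrates",
    "diet_carrion",
    "diet_fruit",
    "diet_nectar_pollen",
    "diet_seeds",
    "diet_other_plant",
]
FORAGING_AXES = [
    "forage_water_below_surface",
    "forage_water_around_surface",
    "forage_ground",
    "forage_understory",
    "forage_mid_canopy",
    "forage_upper_canopy",
    "forage_aerial",
]

EXTINCTION_STATUSES = (
    "Extinct",
    "Extinct in the Wild",
    "Critically Endangered (Possibly Extinct)",
)


@dataclass
class SpeciesParams:
    """Per-species occupancy/detection coefficients plus community hyperparameters.

    All coefficients are on the logit scale: ``beta0`` (occupancy intercept),
    ``beta1`` (slope on standardised elevation), ``alpha0`` (detection
    intercept) and ``trend`` (additive change in logit occupancy per year).
    """

    beta0: np.ndarray
    beta1: np.ndarray
    alpha0: np.ndarray
    trend: np.ndarray
    hyperparams: dict = field(default_factory=dict)
    species_ids: list = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return self.beta0.shape[0]


@dataclass
class DetectionArray:
    """One year of detection histories plus the simulated latent truth.

    ``y`` has shape (species, routes, segments) with binary entries;
    ``z`` has shape (species, routes) and is the latent occupancy state.
    """

    year: int
    y: np.ndarray
    z: np.ndarray
    species_ids: list
    route_ids: list

    def __post_init__(self):
        if self.y.ndim != 3 or self.y.shape[2] != N_SEGMENTS:
            raise ValueError(f"y must be (species, routes, {N_SEGMENTS})")
        if self.y.shape[:2] != self.z.shape:
            raise ValueError("y and z shapes disagree")

    def to_long_frame(self) -> pd.DataFrame:
        s, r, k = np.nonzero(np.ones_like(self.y))
        return pd.DataFrame(
            {
                "species_id": np.asarray(self.species_ids)[s],
                "route_id": np.asarray(self.route_ids)[r],
                "segment": k + 1,
                "y": self.y[s, r, k],
            }
        )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_routes(
    n_routes: int,
    n_bcrs: int,
    extent_km: float = 2000.0,
    seed=0,
    years=None,
    survey_prob: float = 1.0,
    projection: EqualAreaProjection = DEFAULT_PROJECTION,
    origin_lonlat=(-110.0, 32.0),
) -> pd.DataFrame:
    """Scatter survey routes uniformly over a square extent.

    Routes are placed in projected (equal-area) kilometre coordinates over
    ``[0, extent_km]^2`` offset to ``origin_lonlat``, and regional (BCR)
    membership is assigned by vertical spatial blocks.  Elevations are
    lognormal (median ~500 m) and a standardised copy ``elevation_z`` is
    included for the occupancy linear predictor.

    ``surveyed_years`` is the set of years the route was run; with
    ``survey_prob < 1`` interior years are dropped independently, while the
    first and last year are always kept for a random ~90% of routes and the
    remaining routes miss one endpoint (so constant-effort filtering has
    something to remove).
    """
    if n_routes < 1 or n_bcrs < 1 or extent_km <= 0:
        raise ValueError("n_routes, n_bcrs must be >= 1 and extent_km > 0")
    rng = _rng(seed)
    u = rng.uniform(0.0, extent_km, size=n_routes)
    v = rng.uniform(0.0, extent_km, size=n_routes)
    x0, y0 = projection.forward(*origin_lonlat)
    x = np.asarray(x0) + u
    y = np.asarray(y0) + v
    lon, lat = projection.inverse(x, y)
    # vertical strips of equal width; every strip index is guaranteed present
    # only when n_routes >= n_bcrs and draws land in all strips, so force
    # coverage by assigning the first n_bcrs routes one strip each
    bcr = np.minimum((u / extent_km * n_bcrs).astype(int), n_bcrs - 1)
    bcr[: min(n_bcrs, n_routes)] = np.arange(min(n_bcrs, n_routes))
    elevation = rng.lognormal(mean=np.log(500.0), sigma=0.6, size=n_routes)
    elev_z = (elevation - elevation.mean()) / (elevation.std() if n_routes > 1 else 1.0)

    if years is None:
        years = [1969]
    years = sorted(int(t) for t in years)
    surveyed = []
    for i in range(n_routes):
        yrs = {t for t in years if rng.uniform() < survey_prob}
        if rng.uniform() < 0.9 or survey_prob >= 1.0:
            yrs.update({years[0], years[-1]})
        else:
            yrs.discard(years[-1] if rng.uniform() < 0.5 else years[0])
        if not yrs:
            yrs = {years[0], years[-1]}
        surveyed.append(frozenset(yrs))

    return pd.DataFrame(
        {
            "route_id": [f"R{i:04d}" for i in range(n_routes)],
            "median_lat": lat,
            "median_lon": lon,
            "x_km": x,
            "y_km": y,
            "elevation_m": elevation,
            "elevation_z": elev_z,
            "bcr_id": [f"BCR{b + 1:02d}" for b in bcr],
            "surveyed_years": surveyed,
        }
    )


DEFAULT_HYPERPARAMS = {
    "mu_beta0": -1.0,
    "sd_beta0": 1.0,
    "mu_beta1": 0.0,
    "sd_beta1": 0.5,
    "mu_alpha0": 0.0,
    "sd_alpha0": 0.7,
    "mu_trend": 0.0,
    "sd_trend": 0.0,
}


def generate_species_params(n_species: int, hyperparams=None, seed=0) -> SpeciesParams:
    """Draw species-level coefficients from Normal community hyperdistributions.

    ``hyperparams`` updates :data:`DEFAULT_HYPERPARAMS`; SDs must be >= 0
    (strictly positive for the occupancy/detection coefficients; a zero SD is
    allowed and gives the degenerate all-species-identical community, which is
    useful in tests).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        unknown = set(hyperparams) - set(hp)
        if unknown:
            raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")
        hp.update(hyperparams)
    for key, val in hp.items():
        if key.startswith("sd_") and (not np.isfinite(val) or val < 0):
            raise ValueError(f"{key} must be finite and >= 0")
    rng = _rng(seed)
    draw = lambda m, s: rng.normal(hp[m], hp[s], size=n_species)
    return SpeciesParams(
        beta0=draw("mu_beta0", "sd_beta0"),
        beta1=draw("mu_beta1", "sd_beta1"),
        alpha0=draw("mu_alpha0", "sd_alpha0"),
        trend=draw("mu_trend", "sd_trend"),
        hyperparams=hp,
        species_ids=[f"SP{i:04d}" for i in range(n_species)],
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_detection_histories(
    params: SpeciesParams,
    routes: pd.DataFrame,
    years,
    seed=0,
) -> list[DetectionArray]:
    """Forward-simulate detection histories for each year.

    For year t (with t0 the first year), species i and route j:

        logit(psi_ij) = beta0_i + trend_i * (t - t0) + beta1_i * elev_z_j
        z_ij ~ Bernoulli(psi_ij)
        y_ijk ~ Bernoulli(p_i * z_ij),  logit(p_i) = alpha0_i,  k = 1..5

    Routes not surveyed in a year are still simulated (their columns are
    present) so that the latent truth is complete; survey masks are applied by
    the spatial-filtering stage, not here.
    """
    years = sorted(int(t) for t in np.atleast_1d(years))
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    rng = _rng(seed)
    elev = routes["elevation_z"].to_numpy(dtype=float)
    if not np.all(np.isfinite(elev)):
        raise ValueError("non-finite elevation")
    t0 = years[0]
    p = _sigmoid(params.alpha0)[:, None, None]
    out = []
    for t in years:
        logit_psi = (
            params.beta0[:, None]
            + params.trend[:, None] * (t - t0)
            + params.beta1[:, None] * elev[None, :]
        )
        psi = _sigmoid(logit_psi)
        z = (rng.uniform(size=psi.shape) < psi).astype(np.int8)
        y = (rng.uniform(size=(psi.shape[0], psi.shape[1], N_SEGMENTS)) < p * z[:, :, None]).astype(
            np.int8
        )
        out.append(
            DetectionArray(
                year=t,
                y=y,
                z=z,
                species_ids=list(params.species_ids),
                route_ids=list(routes["route_id"]),
            )
        )
    return out


def generate_trait_table(
    n_species: int,
    seed=0,
    species_ids=None,
    guild_concentration: float = 0.0,
    base_alpha: float = 1.0,
) -> pd.DataFrame:
    """Generate body mass plus simplex-constrained diet and foraging blocks.

    Body masses are lognormal (median 30 g, log-SD 1).  Each 7-axis block is
    Dirichlet; ``guild_concentration > 0`` adds that much Dirichlet weight to
    one randomly chosen dominant axis per species per block, concentrating
    species into guilds as it grows.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = _rng(seed)
    if species_ids is None:
        species_ids = [f"SP{i:04d}" for i in range(n_species)]
    mass = rng.lognormal(mean=np.log(30.0), sigma=1.0, size=n_species)

    def block(k=7):
        alpha = np.full((n_species, k), base_alpha, dtype=float)
        if guild_concentration > 0:
            dom = rng.integers(0, k, size=n_species)
            alpha[np.arange(n_species), dom] += guild_concentration
        g = rng.gamma(shape=alpha)
        g = np.where(g.sum(axis=1, keepdims=True) > 0, g, 1.0 / k)
        return g / g.sum(axis=1, keepdims=True)

    diet = block()
    forage = block()
    df = pd.DataFrame({"species_id": species_ids, "body_mass_g": mass})
    df[DIET_AXES] = diet
    df[FORAGING_AXES] = forage
    return df


def generate_global_extinction_fixture(
    n_total: int, n_extinct: int, year_range=(1969, 2013), seed=0, species_ids=None
) -> pd.DataFrame:
    """A small global-extinction record: species, IUCN-style status, year."""
    if not 0 <= n_extinct <= n_total:
        raise ValueError("need 0 <= n_extinct <= n_total")
    rng = _rng(seed)
    if species_ids is None:
        species_ids = [f"SP{i:04d}" for i in range(n_total)]
    chosen = rng.choice(n_total, size=n_extinct, replace=False)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n_extinct)
    statuses = rng.choice(EXTINCTION_STATUSES, size=n_extinct)
    return pd.DataFrame(
        {
            "species_id": [species_ids[i] for i in sorted(chosen)],
            "status": statuses,
            "extinction_year": years,
        }
    )
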