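"""Hierarchical multispecies occupancy model with data augmentation.

One year of detection/non-detection histories ``y[i, j, k]`` (species i,
route j, segment k = 1..5) is modelled as imperfect observation of a latent
occupancy state:

    y_ijk ~ Bernoulli(p_i * z_ij)          logit(p_i)     = alpha0_i
    z_ij  ~ Bernoulli(psi_ij)              logit(psi_ij)  = beta0_i + beta1_i * ELEV_j

with species coefficients pooled through Normal community hyperdistributions,

    beta0_i ~ N(mu_beta0, sd_beta0^2)   (and likewise beta1, alpha0),

and optional parameter-expanded data augmentation: all-zero pseudo-species are
appended up to a superpopulation of size M, each with an inclusion indicator
w_i ~ Bernoulli(Omega), so the community hyperparameters and richness are not
conditioned on the observed species list alone.

Inference is a blocked Metropolis-within-Gibbs sampler: the latent states z,
the inclusion indicators w, Omega, and the hyperparameters have closed-form
full conditionals; the species coefficients are updated by adaptively scaled
random-walk Metropolis steps vectorised across species.  Convergence is
summarised with rank-normalised split R-hat and bulk ESS (via ArviZ) on the
monitored hyperparameters.

The fitted object reports psi_ij as the posterior mean of z_ij — the
conditional probability of presence given the detection history — so any
species-route pair with at least one detection has psi exactly 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .synthetic import N_SEGMENTS, DetectionArray

logger = logging.getLogger(__name__)

_HYPER_NAMES = [
    "mu_beta0", "sd_beta0", "mu_beta1", "sd_beta1", "mu_alpha0", "sd_alpha0", "Omega",
]


def _log1pexp(x):
    # stable log(1 + exp(x))
    out = np.empty_like(x, dtype=float)
    big = x > 33.0
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(x[~big]))
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def conditional_occupancy(psi, p, n_segments=N_SEGMENTS):
    """Probability of presence given no detection in ``n_segments`` replicates.

    Bayes rule for the zero-detection history:
    ``psi * (1-p)^K / (psi * (1-p)^K + 1 - psi)``.
    """
    psi = np.asarray(psi, dtype=float)
    q = (1.0 - np.asarray(p, dtype=float)) ** n_segments
    return psi * q / (psi * q + 1.0 - psi)


@dataclass
class OccupancyConfig:
    """Sampler and prior configuration.

    ``augment`` appends all-zero pseudo-species until the superpopulation has
    ``ceil(m_factor * n_detected)`` members.  ``mu_prior_sd`` is the SD of the
    N(0, .) prior on each community mean; community variances get an
    InverseGamma(``sigma2_a``, ``sigma2_b``) prior.  ``rhat_threshold`` is the
    convergence cutoff applied to monitored hyperparameters.
    """

    chains: int = 3
    draws: int = 2000
    warmup: int = 1000
    augment: bool = True
    m_factor: float = 1.2
    mu_prior_sd: float = 5.0
    sigma2_a: float = 0.5
    sigma2_b: float = 0.5
    rhat_threshold: float = 1.1
    fixed_params: dict | None = None  # {'beta0': arr, 'beta1': arr, 'alpha0': arr}


class MultispeciesOccupancyModel:
    """Single-year community occupancy model.

    Parameters
    ----------
    detections : DetectionArray
        One year of binary histories (species x route x segment).  Species
        with no detections at all are retained — their occupancy is estimated
        through the community hyperdistribution.
    routes : pandas.DataFrame
        Route table carrying ``route_id`` and ``elevation_z`` (standardised
        elevation entering the occupancy linear predictor).
    config : OccupancyConfig, optional
    """

    def __init__(self, detections: DetectionArray, routes: pd.DataFrame, config=None):
        self.config = config or OccupancyConfig()
        self.detections = detections
        route_index = pd.Index(routes["route_id"])
        missing = [r for r in detections.route_ids if r not in route_index]
        if missing:
            raise ValueError(f"routes missing from route table: {missing[:5]}")
        elev = (
            routes.set_index("route_id")["elevation_z"]
            .reindex(detections.route_ids)
            .to_numpy(dtype=float)
        )
        if not np.all(np.isfinite(elev)):
            raise ValueError("non-finite elevation for a detection route")
        if detections.y.sum() == 0:
            raise ValueError("no detections at all: model is unidentifiable")
        self.elev = elev
        self.species_ids = list(detections.species_ids)
        self.route_ids = list(detections.route_ids)
        self.year = detections.year

    # ------------------------------------------------------------------ fit
    def fit(self, seed=0) -> "OccupancyResults":
        cfg = self.config
        y = self.detections.y
        n_listed, J, K = y.shape
        det_count_obs = y.sum(axis=2).astype(float)
        n_detected = int((det_count_obs.sum(axis=1) > 0).sum())
        n_aug = 0
        if cfg.augment:
            m_total = math.ceil(cfg.m_factor * max(n_detected, 1))
            n_aug = max(0, m_total - n_listed)
        M = n_listed + n_aug

        det_count = np.zeros((M, J))
        det_count[:n_listed] = det_count_obs
        det_any = det_count > 0
        s_tot = det_count.sum(axis=1)  # total detections per species
        listed = np.zeros(M, dtype=bool)
        listed[:n_listed] = True

        elev = self.elev
        fixed = cfg.fixed_params

        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(cfg.chains)

        n_keep = cfg.draws
        chains_out = {
            "beta0": np.empty((cfg.chains, n_keep, n_listed)),
            "beta1": np.empty((cfg.chains, n_keep, n_listed)),
            "alpha0": np.empty((cfg.chains, n_keep, n_listed)),
        }
        hyper_out = {h: np.empty((cfg.chains, n_keep)) for h in _HYPER_NAMES}
        d_obs = np.empty((cfg.chains, n_keep))
        d_rep = np.empty((cfg.chains, n_keep))
        richness_out = np.empty((cfg.chains, n_keep))
        z_mean = np.zeros((n_listed, J))

        A2 = cfg.mu_prior_sd**2
        a0, b0 = cfg.sigma2_a, cfg.sigma2_b

        for c in range(cfg.chains):
            rng = np.random.default_rng(chain_seeds[c])
            # initial values
            if fixed is not None:
                beta0 = np.broadcast_to(np.asarray(fixed["beta0"], float), (M,)).copy()
                beta1 = np.broadcast_to(np.asarray(fixed["beta1"], float), (M,)).copy()
                alpha0 = np.broadcast_to(np.asarray(fixed["alpha0"], float), (M,)).copy()
            else:
                beta0 = rng.normal(0, 1, M)
                beta1 = rng.normal(0, 0.5, M)
                alpha0 = rng.normal(0, 1, M)
            mu = {"beta0": 0.0, "beta1": 0.0, "alpha0": 0.0}
            sig2 = {"beta0": 1.0, "beta1": 1.0, "alpha0": 1.0}
            omega = 0.5
            w = np.ones(M)
            z = det_any.astype(float)
            step = {k: np.full(M, 0.3) for k in ("beta0", "beta1", "alpha0")}
            acc = {k: np.zeros(M) for k in step}
            n_adapt = 0

            for it in range(cfg.warmup + cfg.draws):
                eta = beta0[:, None] + beta1[:, None] * elev[None, :]
                psi = _sigmoid(eta)
                p = _sigmoid(alpha0)
                q = (1.0 - p) ** K

                # --- inclusion indicators for augmented pseudo-species
                if n_aug:
                    # marginal (over z) likelihood of an all-zero history
                    ll0 = np.log(1.0 - psi[~listed] + psi[~listed] * q[~listed, None]).sum(axis=1)
                    logodds = np.log(omega) - np.log1p(-omega) + ll0
                    w[~listed] = (rng.uniform(size=n_aug) < _sigmoid(logodds)).astype(float)
                    omega = rng.beta(1.0 + w.sum(), 1.0 + M - w.sum())

                # --- latent occupancy states
                pz = conditional_occupancy(psi, p[:, None], K)
                z = np.where(det_any, 1.0, (rng.uniform(size=(M, J)) < pz).astype(float))
                z *= w[:, None]
                z[det_any] = 1.0

                if fixed is None:
                    # --- species coefficients (random-walk Metropolis, vectorised)
                    def loglik_occ(b0, b1):
                        eta = b0[:, None] + b1[:, None] * elev[None, :]
                        return (z * eta - _log1pexp(eta)).sum(axis=1)

                    cur_ll = loglik_occ(beta0, beta1)
                    for name, vec in (("beta0", beta0), ("beta1", beta1)):
                        prop = vec + step[name] * rng.normal(size=M)
                        prop_ll = (
                            loglik_occ(prop, beta1) if name == "beta0" else loglik_occ(beta0, prop)
                        )
                        dprior = ((vec - mu[name]) ** 2 - (prop - mu[name]) ** 2) / (
                            2.0 * sig2[name]
                        )
                        dlog = np.where(w > 0, prop_ll - cur_ll, 0.0) + dprior
                        accept = np.log(rng.uniform(size=M)) < dlog
                        vec[accept] = prop[accept]
                        cur_ll = np.where(accept, prop_ll, cur_ll)
                        acc[name] += accept

                    # --- detection intercepts
                    n_trials = K * z.sum(axis=1)
                    cur_ll_a = s_tot * alpha0 - n_trials * _log1pexp(alpha0)
                    prop = alpha0 + step["alpha0"] * rng.normal(size=M)
                    prop_ll_a = s_tot * prop - n_trials * _log1pexp(prop)
                    dprior = ((alpha0 - mu["alpha0"]) ** 2 - (prop - mu["alpha0"]) ** 2) / (
                        2.0 * sig2["alpha0"]
                    )
                    accept = np.log(rng.uniform(size=M)) < (prop_ll_a - cur_ll_a + dprior)
                    alpha0[accept] = prop[accept]
                    acc["alpha0"] += accept

                    # --- community hyperparameters (conjugate)
                    for name, vec in (("beta0", beta0), ("beta1", beta1), ("alpha0", alpha0)):
                        prec = M / sig2[name] + 1.0 / A2
                        mean = (vec.sum() / sig2[name]) / prec
                        mu[name] = rng.normal(mean, 1.0 / np.sqrt(prec))
                        sig2[name] = 1.0 / rng.gamma(
                            a0 + 0.5 * M, 1.0 / (b0 + 0.5 * ((vec - mu[name]) ** 2).sum())
                        )

                    # --- step-size adaptation during warmup
                    n_adapt += 1
                    if it < cfg.warmup and n_adapt == 50:
                        for name in step:
                            rate = acc[name] / n_adapt
                            step[name] *= np.exp((rate - 0.44))
                            np.clip(step[name], 1e-3, 10.0, out=step[name])
                            acc[name][:] = 0.0
                        n_adapt = 0

                if it >= cfg.warmup:
                    k = it - cfg.warmup
                    chains_out["beta0"][c, k] = beta0[:n_listed]
                    chains_out["beta1"][c, k] = beta1[:n_listed]
                    chains_out["alpha0"][c, k] = alpha0[:n_listed]
                    for name in ("beta0", "beta1", "alpha0"):
                        hyper_out["mu_" + name][c, k] = mu[name]
                        hyper_out["sd_" + name][c, k] = np.sqrt(sig2[name])
                    hyper_out["Omega"][c, k] = omega
                    richness_out[c, k] = w.sum()
                    z_mean += z[:n_listed]

                    # posterior-predictive discrepancy (segment-count Pearson chi^2
                    # over occupied species-route cells)
                    occ = z > 0
                    mu_cnt = K * p[:, None] * occ
                    var_cnt = K * (p * (1.0 - p))[:, None] * occ
                    var_safe = np.where(occ & (var_cnt > 1e-12), var_cnt, 1.0)
                    d_obs[c, k] = (((det_count - mu_cnt) ** 2 / var_safe) * occ).sum()
                    rep = rng.binomial(K, np.broadcast_to(p[:, None], occ.shape)) * occ
                    d_rep[c, k] = (((rep - mu_cnt) ** 2 / var_safe) * occ).sum()

        z_mean /= cfg.chains * n_keep

        return OccupancyResults(
            model=self,
            coef_draws=chains_out,
            hyper_draws=hyper_out,
            richness_draws=richness_out,
            z_posterior_mean=z_mean,
            d_obs=d_obs,
            d_rep=d_rep,
            n_augmented=n_aug,
            seed=seed,
        )


@dataclass
class OccupancyResults:
    """Posterior summaries and draws from a fitted multispecies occupancy model."""

    model: MultispeciesOccupancyModel
    coef_draws: dict
    hyper_draws: dict
    richness_draws: np.ndarray
    z_posterior_mean: np.ndarray
    d_obs: np.ndarray
    d_rep: np.ndarray
    n_augmented: int
    seed: int
    _idata: object = field(default=None, repr=False)

    # ------------------------------------------------------------ diagnostics
    @property
    def idata(self):
        if self._idata is None:
            data = {k: v for k, v in self.hyper_draws.items()}
            data["richness"] = self.richness_draws
            self._idata = az.from_dict(posterior=data)
        return self._idata

    def diagnostics(self) -> pd.DataFrame:
        """R-hat and bulk ESS for the monitored hyperparameters."""
        rhat = az.rhat(self.idata)
        ess = az.ess(self.idata)
        names = list(self.hyper_draws) + ["richness"]
        return pd.DataFrame(
            {
                "rhat": [float(rhat[n]) for n in names],
                "ess_bulk": [float(ess[n]) for n in names],
            },
            index=names,
        )

    @property
    def converged(self) -> bool:
        # zero-variance chains (e.g. fixed-parameter fits) give NaN R-hat; skip them
        rhat = self.diagnostics()["rhat"].dropna()
        return bool(rhat.empty or rhat.max() < self.model.config.rhat_threshold)

    # ---------------------------------------------------------------- outputs
    def psi_matrix(self) -> pd.DataFrame:
        """Posterior-mean conditional occupancy, species x route.

        Entries for species-route pairs with at least one detection are
        exactly 1 (presence is then known).
        """
        if not self.converged:
            logger.warning(
                "occupancy fit year=%s flagged: max R-hat exceeds %.2f",
                self.model.year,
                self.model.config.rhat_threshold,
            )
        return pd.DataFrame(
            self.z_posterior_mean, index=self.model.species_ids, columns=self.model.route_ids
        )

    def coef_interval(self, name: str, level: float = 0.95) -> pd.DataFrame:
        """Per-species posterior mean and central credible interval."""
        draws = self.coef_draws[name].reshape(-1, self.coef_draws[name].shape[-1])
        lo, hi = np.percentile(draws, [(1 - level) / 2 * 100, (1 + level) / 2 * 100], axis=0)
        return pd.DataFrame(
            {"mean": draws.mean(axis=0), "lower": lo, "upper": hi},
            index=self.model.species_ids,
        )

    def summary(self) -> pd.DataFrame:
        """Posterior summary table for community-level parameters."""
        rows = {}
        for name, d in {**self.hyper_draws, "richness": self.richness_draws}.items():
            flat = np.asarray(d).ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows[name] = {"mean": flat.mean(), "sd": flat.std(), "hdi_2.5%": lo, "hdi_97.5%": hi}
        out = pd.DataFrame(rows).T
        diag = self.diagnostics()
        return out.join(diag)

    def posterior_predictive_check(self) -> "PPCResult":
        """Bayesian p value and discrepancy ratio from the fit's PPC draws.

        The discrepancy is the sum of squared Pearson residuals of
        segment-level detection counts over occupied species-route cells; the
        p value is Pr(D_rep >= D_obs) and the ratio mean(D_rep)/mean(D_obs)
        should both indicate calibration (~0.5 and ~1) for a well-specified
        fit.
        """
        n = self.d_obs.size
        if n < 100:
            raise ValueError("too few posterior draws for a predictive check (< 100)")
        p = float((self.d_rep >= self.d_obs).mean())
        ratio = float(self.d_rep.mean() / self.d_obs.mean())
        return PPCResult(p_value=p, ratio=ratio, n_draws=n)


@dataclass(frozen=True)
class PPCResult:
    p_value: float
    ratio: float
    n_draws: int


def fit_multispecies_occupancy(detections, routes, config=None, seed=0) -> OccupancyResults:
    """Convenience wrapper: build the model and fit it."""
    return MultispeciesOccupancyModel(detections, routes, config).fit(seed=seed)


def estimate_psi(results: OccupancyResults) -> pd.DataFrame:
    """Detection-corrected occupancy matrix (posterior mean of z)."""
    return results.psi_matrix()


def posterior_predictive_check(results: OccupancyResults) -> PPCResult:
    return results.posterior_predictive_check()


def apply_region_constraint(
    psi: pd.DataFrame, detections: DetectionArray, route_bcr_map
) -> pd.DataFrame:
    """Zero occupancy in regions where a species was never detected that year.

    ``psi`` is species x route; ``route_bcr_map`` maps route_id -> region id.
    For each species, every route in a region (BCR) with zero detections of
    that species gets psi = 0; other entries are unchanged.  Idempotent.
    """
    route_bcr_map = dict(route_bcr_map)
    unmapped = [r for r in psi.columns if r not in route_bcr_map]
    if unmapped:
        raise ValueError(f"routes without a BCR: {unmapped[:5]}")
    det = pd.DataFrame(
        detections.y.sum(axis=2), index=detections.species_ids, columns=detections.route_ids
    )
    det = det.reindex(index=psi.index, columns=psi.columns, fill_value=0)
    bcr = pd.Series({r: route_bcr_map[r] for r in psi.columns})
    detected_in_bcr = det.T.groupby(bcr).sum().T > 0  # species x bcr
    allowed = detected_in_bcr.loc[:, bcr.to_numpy()].to_numpy()
    out = psi.copy()
    out.values[~allowed] = 0.0
    return out
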