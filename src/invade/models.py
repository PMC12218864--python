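"""Bayesian habitat-use models: occupancy, daily counts, night activity.

Three models quantify how invasive-cactus density affects mammal habitat use,
each fitted per species, season and exposure scale (site-level % cover or
square-level volume):

* **Occupancy** — a single-season site-occupancy model with imperfect
  detection. Site i is used with probability ψ_i (logit-linear in exposure
  and back-door covariates plus a spatial Gaussian-process term); given use,
  day j yields a detection with probability p_ij (logit-linear in camera-model
  intercept and daily mean temperature). The latent use indicator is
  marginalised out analytically.
* **Counts** — daily detection totals per site-day follow a negative binomial
  (NB2: variance μ + μ²/φ) with a log-linear site mean.
* **Night proportion** — of the n_ij detections on a site-day, the number
  after dusk and before dawn is binomial with a logit-linear probability
  including lunar illumination and an exposure × lunar interaction.

All covariates are standardised (mean 0, sd 1) except lunar illumination,
which stays on its natural [0, 1] scale. Slopes are season-specific. Spatial
autocorrelation enters through a zero-mean Gaussian process over site
coordinates with an exponentiated-quadratic kernel, non-centred for sampling;
its amplitude η and length-scale ρ are updated by Metropolis-within-Gibbs
while everything else uses Hamiltonian Monte Carlo with analytic gradients.

Priors are weakly regularising: slopes ~ Normal(0, 1), intercepts
~ Normal(0, 1.5), η ~ half-Normal(1), ρ ~ half-Normal(half the study extent),
log φ ~ Normal(0, 1.5); camera-model intercepts are hierarchical
Normal(a₀, 1) with a₀ ~ Normal(0, 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special

from .sampler import SampleResult, hmc_sample

__all__ = [
    "ModelSpec",
    "ModelData",
    "PosteriorDraws",
    "standardize_covariates",
    "gp_covariance",
    "occupancy_loglik",
    "nb_loglik",
    "night_loglik",
    "log_posterior",
    "sample_posterior",
    "build_model_data",
]

GP_JITTER = 1e-6

PRIOR_SLOPE_SD = 1.0
PRIOR_INTERCEPT_SD = 1.5
PRIOR_ETA_SCALE = 1.0
PRIOR_CAMERA_SD = 1.0
PRIOR_LOGPHI_SD = 1.5


# ---------------------------------------------------------------------------
# covariate standardization
# ---------------------------------------------------------------------------

def standardize_covariates(
    table: pd.DataFrame, exclude: Sequence[str] = ()
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre and scale numeric columns to mean 0, sd 1 (sample sd, n−1).

    Columns named in ``exclude`` (e.g. lunar illumination) pass through
    untouched. Returns the transformed table and a scaling record
    ``{column: (mean, sd)}`` for back-transforming effect curves.

    Raises ``ValueError`` naming any zero-variance column.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in table.columns:
        if col in exclude or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        mu = float(table[col].mean())
        sd = float(table[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (table[col] - mu) / sd
        scaling[col] = (mu, sd)
    return out, scaling


# ---------------------------------------------------------------------------
# Gaussian process
# ---------------------------------------------------------------------------

def gp_covariance(
    coords: np.ndarray, eta: float, rho: float, jitter: float = GP_JITTER
) -> np.ndarray:
    """Exponentiated-quadratic covariance K_ij = η² exp(−d²/2ρ²) + jitter·I.

    ``coords`` is (n, 2) in metres. The jitter keeps the Cholesky
    factorisation stable when sites nearly coincide.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if eta < 0 or rho <= 0:
        raise ValueError("require eta >= 0 and rho > 0")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return eta**2 * np.exp(-d2 / (2.0 * rho**2)) + jitter * np.eye(len(coords))


def _gp_corr_chol(coords: np.ndarray, rho: float, jitter: float = GP_JITTER) -> np.ndarray:
    """Cholesky factor of the correlation matrix (η factored out)."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    c = np.exp(-d2 / (2.0 * rho**2)) + jitter * np.eye(len(coords))
    try:
        return linalg.cholesky(c, lower=True)
    except linalg.LinAlgError as e:
        raise ValueError(
            f"GP correlation matrix not positive definite at rho={rho} even "
            f"with jitter {jitter}; check for duplicated coordinates"
        ) from e


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _log_expit(x):
    return -np.logaddexp(0.0, -x)


def occupancy_loglik(y: np.ndarray, psi: np.ndarray, p: np.ndarray) -> float:
    """Marginal likelihood of a detection-history matrix.

    ``y`` is (sites, days) with entries {0, 1, NaN} (NaN = camera inactive);
    ``psi`` is (sites,), ``p`` is (sites, days). Sites with at least one
    detection contribute log ψ + Σ log Bern(y|p); all-zero sites contribute
    log(ψ·Π(1−p) + (1−ψ)), evaluated with log-sum-exp stability.
    """
    y = np.asarray(y, dtype=float)
    psi = np.asarray(psi, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((psi <= 0) | (psi >= 1)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("psi and p must lie strictly in (0, 1)")
    obs = ~np.isnan(y)
    yv = np.where(obs, y, 0.0)
    log_p = np.log(p)
    log_q = np.log1p(-p)
    site_det = np.nansum(y, axis=1) > 0

    bern = np.where(obs, yv * log_p + (1 - yv) * log_q, 0.0).sum(axis=1)
    ll_det = np.log(psi) + bern
    # all-zero sites: bern == sum log(1-p) over observed days
    ll_nodet = np.logaddexp(np.log(psi) + bern, np.log1p(-psi))
    return float(np.where(site_det, ll_det, ll_nodet).sum())


def nb_loglik(counts: np.ndarray, mu, phi: float) -> float:
    """NB2 log-likelihood: Σ log NB(n | μ, φ), variance μ + μ²/φ.

    NaN entries in ``counts`` (inactive days) are skipped. Counts must be
    non-negative integers.
    """
    counts = np.asarray(counts, dtype=float)
    obs = ~np.isnan(counts)
    n = counts[obs]
    if np.any(n < 0) or np.any(n != np.round(n)):
        raise ValueError("counts must be non-negative integers")
    if phi <= 0:
        raise ValueError("dispersion phi must be positive")
    mu = np.broadcast_to(np.asarray(mu, dtype=float), counts.shape)[obs]
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    ll = (
        special.gammaln(n + phi)
        - special.gammaln(phi)
        - special.gammaln(n + 1.0)
        + phi * np.log(phi / (phi + mu))
        + n * np.log(mu / (phi + mu))
    )
    return float(ll.sum())


def night_loglik(k: np.ndarray, n: np.ndarray, linear_predictor: np.ndarray) -> float:
    """Binomial log-likelihood for night-time detection proportions.

    ``k`` night detections of ``n`` total per site-day; rows with n = 0 (or
    NaN) contribute exactly 0. The success probability is
    logistic(linear_predictor).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    c = np.broadcast_to(np.asarray(linear_predictor, dtype=float), k.shape)
    obs = ~(np.isnan(k) | np.isnan(n)) & (n > 0)
    kk, nn, cc = k[obs], n[obs], c[obs]
    if np.any(kk > nn) or np.any(kk < 0):
        raise ValueError("require 0 <= k <= n")
    ll = (
        special.gammaln(nn + 1.0)
        - special.gammaln(kk + 1.0)
        - special.gammaln(nn - kk + 1.0)
        + kk * _log_expit(cc)
        + (nn - kk) * _log_expit(-cc)
    )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# model spec / data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response family, exposure scale and covariate structure."""

    response: str  # occupancy | count | night
    exposure: str = "opuntia_cover_pct"
    covariates: tuple[str, ...] = ()
    season_specific: bool = True
    gp: bool = True
    lunar_interaction: bool = True  # night model only
    jitter: float = GP_JITTER

    def __post_init__(self) -> None:
        if self.response not in ("occupancy", "count", "night"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.exposure in self.covariates:
            raise ValueError("exposure must not be repeated in covariates")


@dataclass
class ModelData:
    """Arrays for one species × season-set fit (sites × days layout)."""

    X: np.ndarray  # (n_sites, 1 + n_covariates), exposure first, standardized
    season: np.ndarray  # (n_sites,) codes 0..S-1
    coords: np.ndarray  # (n_sites, 2) metres
    camera: np.ndarray  # (n_sites,) codes 0..M-1
    y: np.ndarray | None = None  # (sites, days) 0/1/NaN
    counts: np.ndarray | None = None  # (sites, days) for count + night models
    night_counts: np.ndarray | None = None
    temp: np.ndarray | None = None  # (sites, days) standardized
    lunar: np.ndarray | None = None  # (sites, days) raw [0, 1]
    scaling: dict = field(default_factory=dict)
    site_ids: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def n_seasons(self) -> int:
        return int(self.season.max()) + 1

    @property
    def n_cameras(self) -> int:
        return int(self.camera.max()) + 1

    @property
    def extent(self) -> float:
        span = self.coords.max(axis=0) - self.coords.min(axis=0)
        return float(max(np.hypot(*span), 1.0))


def build_model_data(
    sites: pd.DataFrame,
    observations: pd.DataFrame,
    spec: ModelSpec,
) -> ModelData:
    """Assemble standardized fitting arrays from the sites/observations tables.

    Sites with a missing exposure value (e.g. unsurveyed squares in the
    square-volume models) are dropped. Covariates and daily temperature are
    standardized; lunar illumination never is.
    """
    cols = [spec.exposure, *spec.covariates]
    s = sites.dropna(subset=[spec.exposure]).reset_index(drop=True)
    std, scaling = standardize_covariates(s[cols])
    X = std.to_numpy(float)

    season_codes = pd.Categorical(s["season"]).codes if spec.season_specific else np.zeros(len(s), int)
    cam_codes = pd.Categorical(s.get("camera_model", pd.Series(["cam"] * len(s)))).codes

    obs = observations[observations["site_id"].isin(s["site_id"])]
    piv = lambda col: (
        obs.pivot_table(index="site_id", columns="date", values=col, aggfunc="first", dropna=False)
        .reindex(s["site_id"])
        .to_numpy(float)
    )
    y = piv("detected") if "detected" in obs.columns else None
    counts = piv("count") if "count" in obs.columns else None
    nights = piv("night_count") if "night_count" in obs.columns else None
    temp = piv("temp_c") if "temp_c" in obs.columns else None
    lunar = piv("lunar_frac") if "lunar_frac" in obs.columns else None
    if temp is not None:
        tmu = np.nanmean(temp)
        tsd = np.nanstd(temp, ddof=1)
        temp = (temp - tmu) / tsd
        scaling["temp_c"] = (float(tmu), float(tsd))

    return ModelData(
        X=X,
        season=np.asarray(season_codes, int),
        coords=s[["easting_m", "northing_m"]].to_numpy(float),
        camera=np.asarray(cam_codes, int),
        y=y,
        counts=counts,
        night_counts=nights,
        temp=temp,
        lunar=lunar,
        scaling=scaling,
        site_ids=list(s["site_id"]),
    )


# ---------------------------------------------------------------------------
# posterior construction
# ---------------------------------------------------------------------------

class _ModelCore:
    """Parameter packing and logp/gradient evaluation for one ModelSpec."""

    def __init__(self, spec: ModelSpec, data: ModelData):
        self.spec = spec
        self.data = data
        S, K = data.n_seasons, data.X.shape[1]
        self.S, self.K = S, K
        names = ["alpha"]
        cols = [spec.exposure, *spec.covariates]
        for s in range(S):
            for c in cols:
                names.append(f"beta[{c},s{s + 1}]")
        if spec.response == "occupancy":
            names.append("a0")
            names += [f"a_cam[{m}]" for m in range(data.n_cameras)]
            names.append("gamma_temp")
        if spec.response == "count":
            names.append("log_phi")
        if spec.response == "night":
            for s in range(S):
                names.append(f"beta_lunar[s{s + 1}]")
            if spec.lunar_interaction:
                for s in range(S):
                    names.append(f"beta_op_lunar[s{s + 1}]")
        if spec.gp:
            names += [f"u[{i}]" for i in range(data.n_sites)]
        self.hmc_names = names
        self.aux_names = ["gp_eta", "gp_rho"] if spec.gp else []
        self.dim = len(names)
        self.rho_scale = data.extent / 2.0
        self._chol_cache: tuple[float, np.ndarray] | None = None

        # index bookkeeping
        i = 1 + S * K
        self.sl_beta = slice(1, i)
        if spec.response == "occupancy":
            self.i_a0 = i
            self.sl_cam = slice(i + 1, i + 1 + data.n_cameras)
            self.i_gamma = i + 1 + data.n_cameras
            i = self.i_gamma + 1
        if spec.response == "count":
            self.i_logphi = i
            i += 1
        if spec.response == "night":
            self.sl_lunar = slice(i, i + S)
            i += S
            if spec.lunar_interaction:
                self.sl_oplunar = slice(i, i + S)
                i += S
        if spec.gp:
            self.sl_u = slice(i, i + data.n_sites)
            i += data.n_sites
        assert i == self.dim

    # -- GP helpers --
    def chol(self, rho: float) -> np.ndarray:
        if self._chol_cache is not None and self._chol_cache[0] == rho:
            return self._chol_cache[1]
        L = _gp_corr_chol(self.data.coords, rho, self.spec.jitter)
        self._chol_cache = (rho, L)
        return L

    def site_linpred(self, theta: np.ndarray, aux: np.ndarray | None):
        """Site-level linear predictor a_i and the GP field f_i."""
        d = self.data
        beta = theta[self.sl_beta].reshape(self.S, self.K)
        a = theta[0] + (d.X * beta[d.season]).sum(axis=1)
        if self.spec.gp:
            eta, rho = aux
            f = eta * (self.chol(rho) @ theta[self.sl_u])
            a = a + f
        return a

    def _beta_grad(self, dl_da: np.ndarray) -> np.ndarray:
        d = self.data
        g = np.zeros((self.S, self.K))
        for s in range(self.S):
            m = d.season == s
            g[s] = dl_da[m] @ d.X[m]
        return g.ravel()

    def _gp_grad(self, dl_df: np.ndarray, theta, aux) -> np.ndarray:
        eta, rho = aux
        return eta * (self.chol(rho).T @ dl_df) - theta[self.sl_u]

    def _aux_logprior(self, aux) -> float:
        eta, rho = aux
        if eta < 0 or rho <= 0:
            return -math.inf
        return -0.5 * (eta / PRIOR_ETA_SCALE) ** 2 - 0.5 * (rho / self.rho_scale) ** 2

    # -- the full log posterior and gradient --
    def logp_grad(self, theta: np.ndarray, aux: np.ndarray | None = None):
        if np.any(np.abs(theta) > 1e3):
            return -math.inf, np.zeros(self.dim)
        spec, d = self.spec, self.data
        grad = np.zeros(self.dim)

        a = self.site_linpred(theta, aux)
        a = np.clip(a, -35.0, 35.0)

        if spec.response == "occupancy":
            lp, dl_da, dextra = self._occupancy_terms(theta, a, grad)
        elif spec.response == "count":
            lp, dl_da = self._count_terms(theta, a, grad)
        else:
            lp, dl_da = self._night_terms(theta, a, grad)

        # shared structure: intercept, slopes, GP
        grad[0] += dl_da.sum() - theta[0] / PRIOR_INTERCEPT_SD**2
        lp -= 0.5 * (theta[0] / PRIOR_INTERCEPT_SD) ** 2
        beta = theta[self.sl_beta]
        grad[self.sl_beta] += self._beta_grad(dl_da) - beta / PRIOR_SLOPE_SD**2
        lp -= 0.5 * float(beta @ beta) / PRIOR_SLOPE_SD**2
        if spec.gp:
            u = theta[self.sl_u]
            grad[self.sl_u] += self._gp_grad(dl_da, theta, aux)
            lp -= 0.5 * float(u @ u)
            lp += self._aux_logprior(aux)
        if not np.isfinite(lp):
            return -math.inf, np.zeros(self.dim)
        return lp, grad

    def _occupancy_terms(self, theta, a, grad):
        d = self.data
        psi = special.expit(a)
        b = theta[self.sl_cam][d.camera][:, None] + theta[self.i_gamma] * np.nan_to_num(d.temp)
        b = np.clip(b, -35.0, 35.0)
        p = special.expit(b)
        obs = ~np.isnan(d.y)
        yv = np.where(obs, np.nan_to_num(d.y), 0.0)
        log_p, log_q = _log_expit(b), _log_expit(-b)
        bern = np.where(obs, yv * log_p + (1 - yv) * log_q, 0.0).sum(axis=1)
        det = np.nansum(d.y, axis=1) > 0

        log_psi = _log_expit(a)
        log_1mpsi = _log_expit(-a)
        ll_det = log_psi + bern
        ll_nodet = np.logaddexp(log_psi + bern, log_1mpsi)
        lp = float(np.where(det, ll_det, ll_nodet).sum())

        # site-level gradient wrt a
        denom_log = ll_nodet
        w = np.exp(log_psi + bern - denom_log)  # P(occupied | all-zero history)
        dl_da = np.where(det, 1.0 - psi, w - psi)
        # day-level gradient wrt b
        dl_db = np.where(obs, yv - p, 0.0)
        dl_db[~det] = (np.where(obs, -p, 0.0) * w[:, None])[~det]

        # camera intercepts (hierarchical) + temperature slope
        a0 = theta[self.i_a0]
        acam = theta[self.sl_cam]
        for m in range(d.n_cameras):
            grad[self.sl_cam.start + m] += dl_db[d.camera == m].sum()
        grad[self.sl_cam] += -(acam - a0) / PRIOR_CAMERA_SD**2
        grad[self.i_a0] += ((acam - a0) / PRIOR_CAMERA_SD**2).sum() - a0 / PRIOR_INTERCEPT_SD**2
        grad[self.i_gamma] += float((dl_db * np.nan_to_num(d.temp))[obs].sum()) - theta[self.i_gamma] / PRIOR_SLOPE_SD**2
        lp -= 0.5 * float((((acam - a0) / PRIOR_CAMERA_SD) ** 2).sum())
        lp -= 0.5 * (a0 / PRIOR_INTERCEPT_SD) ** 2
        lp -= 0.5 * (theta[self.i_gamma] / PRIOR_SLOPE_SD) ** 2
        return lp, dl_da, None

    def _count_terms(self, theta, a, grad):
        d = self.data
        log_phi = theta[self.i_logphi]
        if abs(log_phi) > 30:
            return -math.inf, np.zeros(d.n_sites)
        phi = math.exp(log_phi)
        mu = np.exp(a)[:, None]
        obs = ~np.isnan(d.counts)
        n = np.where(obs, np.nan_to_num(d.counts), 0.0)
        log_mu = a[:, None]  # exact log of mu, safe at the clip boundary
        log_phimu = np.log(phi + mu)
        ll = np.where(
            obs,
            special.gammaln(n + phi) - special.gammaln(phi) - special.gammaln(n + 1.0)
            + phi * (log_phi - log_phimu) + n * (log_mu - log_phimu),
            0.0,
        )
        lp = float(ll.sum())
        dl_dmu_term = np.where(obs, phi * (n - mu) / (phi + mu), 0.0)
        dl_da = dl_dmu_term.sum(axis=1)
        dl_dlogphi = np.where(
            obs,
            special.digamma(n + phi) - special.digamma(phi)
            + (log_phi - log_phimu) + 1.0 - (n + phi) / (phi + mu),
            0.0,
        ).sum() * phi
        grad[self.i_logphi] += dl_dlogphi - log_phi / PRIOR_LOGPHI_SD**2
        lp -= 0.5 * (log_phi / PRIOR_LOGPHI_SD) ** 2
        return lp, dl_da

    def _night_terms(self, theta, a, grad):
        d = self.data
        S = self.S
        bl = theta[self.sl_lunar][d.season][:, None]
        c = a[:, None] + bl * np.nan_to_num(d.lunar)
        if self.spec.lunar_interaction:
            bol = theta[self.sl_oplunar][d.season][:, None]
            oplun = d.X[:, 0][:, None] * np.nan_to_num(d.lunar)
            c = c + bol * oplun
        c = np.clip(c, -35.0, 35.0)
        obs = ~(np.isnan(d.counts) | np.isnan(d.night_counts)) & (np.nan_to_num(d.counts) > 0)
        n = np.where(obs, np.nan_to_num(d.counts), 0.0)
        k = np.where(obs, np.nan_to_num(d.night_counts), 0.0)
        pi = special.expit(c)
        ll = np.where(
            obs,
            special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
            + k * _log_expit(c) + (n - k) * _log_expit(-c),
            0.0,
        )
        lp = float(ll.sum())
        dl_dc = np.where(obs, k - n * pi, 0.0)
        dl_da = dl_dc.sum(axis=1)
        lun = np.nan_to_num(d.lunar)
        for s in range(S):
            m = d.season == s
            grad[self.sl_lunar.start + s] += float((dl_dc[m] * lun[m]).sum())
            if self.spec.lunar_interaction:
                grad[self.sl_oplunar.start + s] += float(
                    (dl_dc[m] * lun[m] * d.X[m, 0][:, None]).sum()
                )
        bl_flat = theta[self.sl_lunar]
        grad[self.sl_lunar] += -bl_flat / PRIOR_SLOPE_SD**2
        lp -= 0.5 * float(bl_flat @ bl_flat) / PRIOR_SLOPE_SD**2
        if self.spec.lunar_interaction:
            bo = theta[self.sl_oplunar]
            grad[self.sl_oplunar] += -bo / PRIOR_SLOPE_SD**2
            lp -= 0.5 * float(bo @ bo) / PRIOR_SLOPE_SD**2
        return lp, dl_da


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws: (chain, iteration, parameter) with a name registry."""

    draws: np.ndarray
    names: list[str]
    warmup: int
    seed: int
    divergences: np.ndarray
    accept_rate: np.ndarray
    spec: ModelSpec | None = None
    scaling: dict = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, iters)."""
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {self.names[:8]}..."
            ) from None
        return self.draws[:, :, i]

    def pooled(self, name: str) -> np.ndarray:
        """Post-warmup draws pooled across chains (1-d)."""
        return self.get(name).ravel()

    def diagnostics(self) -> pd.DataFrame:
        from .sampler import ess, split_rhat

        rows = [
            {"parameter": nm, "rhat": split_rhat(self.draws[:, :, i]),
             "ess": ess(self.draws[:, :, i])}
            for i, nm in enumerate(self.names)
        ]
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long format (chain, iter, parameter, value) for the draws CSV."""
        C, I, P = self.draws.shape
        ch, it, pi = np.meshgrid(np.arange(C), np.arange(I), np.arange(P), indexing="ij")
        return pd.DataFrame(
            {
                "chain": ch.ravel(),
                "iter": it.ravel(),
                "parameter": np.asarray(self.names)[pi.ravel()],
                "value": self.draws.ravel(),
            }
        )


def log_posterior(
    spec: ModelSpec, params: Mapping[str, float] | np.ndarray, data: ModelData,
    gp_eta: float | None = None, gp_rho: float | None = None,
) -> float:
    """Log posterior density at a named parameter point (for testing/oracles).

    ``params`` is either the packed vector or a mapping from the parameter
    names used by :func:`sample_posterior` to values. GP hyperparameters are
    passed separately when the spec has the GP enabled.
    """
    core = _ModelCore(spec, data)
    if isinstance(params, Mapping):
        theta = np.zeros(core.dim)
        unknown = set(params) - set(core.hmc_names)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        for i, nm in enumerate(core.hmc_names):
            theta[i] = params.get(nm, 0.0)
    else:
        theta = np.asarray(params, dtype=float)
        if theta.size != core.dim:
            raise ValueError(f"expected {core.dim} parameters ({core.hmc_names}), got {theta.size}")
    aux = np.array([gp_eta, gp_rho]) if spec.gp else None
    if spec.gp and (gp_eta is None or gp_rho is None):
        raise ValueError("gp_eta and gp_rho are required when the spec has gp=True")
    lp, _ = core.logp_grad(theta, aux)
    return lp


def sample_posterior(
    spec: ModelSpec,
    data: ModelData,
    chains: int = 4,
    warmup: int | None = None,
    iters: int = 2000,
    seed: int = 0,
    check: bool = True,
) -> PosteriorDraws:
    """Fit a habitat-use model by MCMC and return labelled draws.

    Default warmup follows the fitting protocol: 4000 iterations for the
    occupancy and night (binomial) models, 7000 for the negative-binomial
    count model; 4 chains × 2000 sampling iterations. A ``ConvergenceWarning``
    is raised (not an error) when any split-R̂ exceeds 1.01.
    """
    if warmup is None:
        warmup = 7000 if spec.response == "count" else 4000
    core = _ModelCore(spec, data)
    aux_init = np.array([0.5, core.rho_scale / 2.0]) if spec.gp else None
    res: SampleResult = hmc_sample(
        core.logp_grad,
        np.zeros(core.dim),
        chains=chains,
        warmup=warmup,
        iters=iters,
        seed=seed,
        init_jitter=0.1,
        aux_init=aux_init,
        aux_positive=True,
        param_names=core.hmc_names + core.aux_names,
    )
    out = PosteriorDraws(
        draws=res.draws,
        names=core.hmc_names + core.aux_names,
        warmup=warmup,
        seed=seed,
        divergences=res.divergences,
        accept_rate=res.accept_rate,
        spec=spec,
        scaling=dict(data.scaling),
    )
    if check:
        # only flag the interpretable parameters; per-site GP field noise is
        # expected to mix more slowly
        import warnings as _w

        from .sampler import ConvergenceWarning, split_rhat

        flag = [n for n in core.hmc_names if not n.startswith("u[")]
        bad = {}
        for nm in flag:
            r = split_rhat(out.get(nm))
            if np.isfinite(r) and r > 1.01:
                bad[nm] = r
        if bad:
            worst = max(bad, key=bad.get)
            _w.warn(
                f"{len(bad)} parameter(s) with split-R-hat > 1.01 "
                f"(worst: {worst} = {bad[worst]:.3f})",
                ConvergenceWarning,
                stacklevel=2,
            )
    return out
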