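"""Synthetic camera-trap studies with known ground truth.

The generator reproduces the study design end-to-end so that every pipeline
stage can be validated by parameter recovery: paired sites inside 500 × 500 m
grid squares (one camera at visibly high invasive-cactus density, a second
50–70 m away at strictly lower density), two survey seasons, daily
detection/count/night-count series per site driven by the same three models
the package fits (occupancy with imperfect detection, negative-binomial daily
counts, binomial night proportion, all with a spatial Gaussian-process term),
line-transect distance-sampling counts in three size classes, and per-image
volunteer vote vectors drawn from a stated confusion structure.

The defaults mirror the field deployment: 46 squares in the January–April
season and 14 in October–November (two cameras per square — the field study's
101 + 27 sites reflect camera losses; the generator always emits exactly 2
per square). The number of survey days per camera is a free parameter
(default 60) since deployment lengths varied.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import solar
from .models import gp_covariance

__all__ = [
    "FOCAL_SPECIES",
    "TrueParameters",
    "StudyDesign",
    "SyntheticDataset",
    "generate_design",
    "simulate_site_covariates",
    "simulate_observations",
    "simulate_transects",
    "simulate_votes",
    "generate_dataset",
]

FOCAL_SPECIES = (
    "olive_baboon", "vervet_monkey", "elephant", "buffalo", "dik_dik",
    "impala", "kudu", "giraffe", "grevys_zebra", "plains_zebra",
    "spotted_hyena", "leopard",
)

VOTE_LABELS = FOCAL_SPECIES + ("livestock", "empty")

#: Logit values beyond this are treated as probability 0/1 (double precision).
LOGIT_CAP = 35.0

SEASON_START = {1: date(2021, 1, 15), 2: date(2021, 10, 5)}
CAMERA_MODELS = ("browning", "bushnell")

#: Study-area reference coordinates (deg) used for sun/moon covariates.
STUDY_LAT, STUDY_LON = 0.3, 36.9


def _default_confusion() -> dict[str, dict[str, float]]:
    """0.9 probability of the correct label, 0.1 of an 'empty' vote."""
    conf = {}
    for sp in VOTE_LABELS:
        row = {sp: 0.9, "empty": 0.1} if sp != "empty" else {"empty": 1.0}
        conf[sp] = row
    return conf


@dataclass
class TrueParameters:
    """Generative parameters for one focal species.

    Logit-scale parameters for occupancy/detection/night models, log-scale for
    the count model; slope pairs are (season 1, season 2). ``gp_eta`` (logit
    or log units) and ``gp_rho`` (metres) control the spatial field shared in
    structure across the three responses (independent field draws per
    response). Distance-sampling σ (metres) and stand density (stands per
    square within the truncation strip) are per size class.
    """

    occ_intercept: float = 0.2
    occ_opuntia: tuple[float, float] = (0.75, 0.75)
    det_intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"browning": -0.4, "bushnell": -0.8}
    )
    det_temp: float = 0.3
    count_intercept: float = -1.0
    count_opuntia: tuple[float, float] = (0.4, 0.4)
    count_dispersion: float = 1.0
    night_intercept: float = 0.3
    night_opuntia: tuple[float, float] = (0.3, 0.3)
    night_lunar: float = -0.6
    night_opuntia_lunar: float = -0.3
    gp_eta: float = 0.5
    gp_rho: float = 1000.0
    gp_jitter: float = 1e-6
    ds_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"S": 2.0, "M": 4.0, "L": 6.0}
    )
    ds_density: Mapping[str, float] = field(
        default_factory=lambda: {"S": 30.0, "M": 20.0, "L": 10.0}
    )
    cover_volume_corr: float = 0.6
    confusion: Mapping[str, Mapping[str, float]] = field(default_factory=_default_confusion)

    def validate(self) -> None:
        if self.count_dispersion <= 0:
            raise ValueError("count dispersion phi must be > 0")
        if self.gp_rho <= 0 or self.gp_eta < 0:
            raise ValueError("require gp_rho > 0 and gp_eta >= 0")
        if any(s < 0 for s in self.ds_sigma.values()):
            raise ValueError("distance-sampling sigma must be >= 0")
        if any(d < 0 for d in self.ds_density.values()):
            raise ValueError("stand densities must be >= 0")
        if not -1.0 <= self.cover_volume_corr <= 1.0:
            raise ValueError("cover_volume_corr must lie in [-1, 1]")
        for true_label, row in self.confusion.items():
            probs = np.asarray(list(row.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"confusion row {true_label!r} has probabilities outside [0,1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"confusion row {true_label!r} does not sum to 1")

    def to_json(self) -> dict:
        d = asdict(self)
        d["det_intercepts"] = dict(self.det_intercepts)
        d["ds_sigma"] = dict(self.ds_sigma)
        d["ds_density"] = dict(self.ds_density)
        d["confusion"] = {k: dict(v) for k, v in self.confusion.items()}
        return d


@dataclass
class StudyDesign:
    """Layout of squares, paired sites and survey effort."""

    sites: pd.DataFrame  # site_id, square_id, season, easting_m, northing_m, camera_model
    squares: pd.DataFrame  # square_id, season, origin_e, origin_n
    days: int
    square_edge_m: float = 500.0
    pair_offset_m: tuple[float, float] = (50.0, 70.0)
    bin_breaks_m: np.ndarray = field(default_factory=lambda: np.arange(0.0, 11.0, 1.0))
    transect_length_m: float = 500.0

    def validate(self) -> None:
        lo, hi = self.pair_offset_m
        if self.square_edge_m <= 2 * hi:
            raise ValueError("square edge must exceed twice the max pair offset")
        for sq, grp in self.sites.groupby("square_id"):
            if len(grp) != 2:
                raise ValueError(f"square {sq} does not have exactly 2 sites")
            xy = grp[["easting_m", "northing_m"]].to_numpy(float)
            d = float(np.hypot(*(xy[0] - xy[1])))
            if not (lo - 1e-9 <= d <= hi + 1e-9):
                raise ValueError(f"pair distance {d:.2f} m in square {sq} outside [{lo}, {hi}]")
            orig = self.squares.set_index("square_id").loc[sq, ["origin_e", "origin_n"]].to_numpy(float)
            rel = xy - orig
            if np.any(rel < 0) or np.any(rel > self.square_edge_m):
                raise ValueError(f"sites of square {sq} fall outside their square")


def generate_design(
    n_squares_s1: int = 46,
    n_squares_s2: int = 14,
    days: int = 60,
    seed: int = 0,
    square_edge_m: float = 500.0,
    pair_offset_m: tuple[float, float] = (50.0, 70.0),
) -> StudyDesign:
    """Place grid squares and paired camera sites; deterministic given seed.

    Each square holds exactly two sites: the first at a uniform position
    inside the square's interior, the second at a uniform random bearing and
    a distance drawn uniformly from ``pair_offset_m``.
    """
    if n_squares_s1 < 1 or days < 1 or n_squares_s2 < 0:
        raise ValueError("need n_squares_s1 >= 1, n_squares_s2 >= 0, days >= 1")
    rng = np.random.default_rng([seed, 101])
    n_total = n_squares_s1 + n_squares_s2

    # squares occupy distinct cells of a coarse grid covering the study area
    grid = max(8, math.ceil(math.sqrt(n_total) * 2))
    cells = rng.choice(grid * grid, size=n_total, replace=False)
    ce, cn = cells % grid, cells // grid

    lo, hi = pair_offset_m
    margin = hi + 30.0
    sq_rows, site_rows = [], []
    for i in range(n_total):
        season = 1 if i < n_squares_s1 else 2
        sq_id = f"sq{i + 1:03d}"
        oe, on = float(ce[i] * square_edge_m), float(cn[i] * square_edge_m)
        sq_rows.append(dict(square_id=sq_id, season=season, origin_e=oe, origin_n=on))
        x1 = oe + rng.uniform(margin, square_edge_m - margin)
        y1 = on + rng.uniform(margin, square_edge_m - margin)
        dist = rng.uniform(lo, hi)
        bearing = rng.uniform(0.0, 2.0 * math.pi)
        x2 = x1 + dist * math.sin(bearing)
        y2 = y1 + dist * math.cos(bearing)
        for j, (x, y) in enumerate([(x1, y1), (x2, y2)], start=1):
            site_rows.append(
                dict(
                    site_id=f"{sq_id}_s{j}",
                    square_id=sq_id,
                    season=season,
                    easting_m=x,
                    northing_m=y,
                    camera_model=CAMERA_MODELS[int(rng.integers(len(CAMERA_MODELS)))],
                )
            )
    design = StudyDesign(
        sites=pd.DataFrame(site_rows),
        squares=pd.DataFrame(sq_rows),
        days=days,
        square_edge_m=square_edge_m,
        pair_offset_m=pair_offset_m,
    )
    design.validate()
    return design


def simulate_site_covariates(
    design: StudyDesign, params: TrueParameters, seed: int = 0
) -> pd.DataFrame:
    """Draw habitat covariates per site; returns the sites table.

    Within each pair the first site's cactus cover is strictly greater than
    the second's (site-2 cover is resampled until lower). Square-level volume
    per metre of transect is positively correlated (``cover_volume_corr``)
    with the square's mean site cover. Percentage covers are independent and
    not constrained to sum to 100.
    """
    params.validate()
    rng = np.random.default_rng([seed, 202])
    n = len(design.sites)
    df = design.sites.copy()

    cover1 = rng.uniform(30.0, 90.0, n // 2)
    cover2 = np.empty(n // 2)
    for i, c1 in enumerate(cover1):
        c2 = rng.uniform(0.0, 90.0)
        while c2 >= c1:
            c2 = rng.uniform(0.0, 90.0)
        cover2[i] = c2
    cover = np.empty(n)
    cover[0::2], cover[1::2] = cover1, cover2
    df["opuntia_cover_pct"] = cover

    df["grass_pct"] = rng.uniform(5.0, 80.0, n)
    df["shrub_pct"] = rng.uniform(0.0, 60.0, n)
    df["forb_pct"] = rng.uniform(0.0, 40.0, n)
    df["succulent_pct"] = rng.uniform(0.0, 30.0, n)
    df["tree_count"] = rng.poisson(4.0, n)
    df["dist_river_m"] = rng.uniform(50.0, 3000.0, n)
    df["dist_road_m"] = rng.uniform(50.0, 5000.0, n)
    df["livestock_prop"] = rng.beta(1.5, 5.0, n)

    # square volume: lognormal, Gaussian-copula correlated with mean cover
    mean_cov = df.groupby("square_id")["opuntia_cover_pct"].mean()
    z = (mean_cov - mean_cov.mean()) / max(mean_cov.std(ddof=1), 1e-9)
    r = params.cover_volume_corr
    eps = rng.standard_normal(len(mean_cov))
    vol_per_m = np.exp(-2.5 + 0.8 * (r * z.to_numpy() + math.sqrt(max(0.0, 1 - r**2)) * eps))
    df["square_opuntia_vol_m3_per_m"] = df["square_id"].map(
        pd.Series(vol_per_m, index=mean_cov.index)
    )
    return df


def _season_dates(season: int, days: int) -> list[date]:
    start = SEASON_START[season]
    return [start + timedelta(days=k) for k in range(days)]


def _lunar_series(dates: Sequence[date], tz_offset: float = 3.0) -> np.ndarray:
    """Illuminated lunar fraction at local midnight of each date."""
    out = np.empty(len(dates))
    for i, d in enumerate(dates):
        local_mid = datetime(d.year, d.month, d.day, tzinfo=timezone.utc) - timedelta(
            hours=tz_offset
        )
        out[i] = solar.lunar_fraction(local_mid)
    return out


def simulate_observations(
    sites: pd.DataFrame,
    params: TrueParameters,
    days: int = 60,
    seed: int = 0,
    inactive_prob: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the daily observation series and return it with latent truth.

    Per site-day: ``detected`` ~ Bernoulli(z·p) from the occupancy process,
    ``count`` ~ NegBin(μ, φ), ``night_count`` ~ Binomial(count, π) with the
    exposure × lunar interaction, plus daily mean temperature and the lunar
    illuminated fraction at local midnight. ``inactive_prob`` masks site-days
    as NA (camera downtime). Latent truth holds z, the three GP field draws,
    and the standardization constants used for the exposure.
    """
    params.validate()
    rng = np.random.default_rng([seed, 303])
    n = len(sites)
    coords = sites[["easting_m", "northing_m"]].to_numpy(float)
    season = sites["season"].to_numpy(int)
    s_idx = season - 1

    cov = sites["opuntia_cover_pct"].to_numpy(float)
    cov_mu, cov_sd = float(cov.mean()), float(cov.std(ddof=1))
    x = (cov - cov_mu) / cov_sd

    K = gp_covariance(coords, params.gp_eta, params.gp_rho, params.gp_jitter)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "GP covariance not positive definite after jitter "
            f"{params.gp_jitter}; check coordinates/params"
        ) from e
    f_occ, f_cnt, f_night = (L @ rng.standard_normal(n) for _ in range(3))

    occ_beta = np.asarray(params.occ_opuntia)[s_idx]
    logit_psi = np.clip(params.occ_intercept + occ_beta * x + f_occ, -LOGIT_CAP, LOGIT_CAP)
    from scipy.special import expit

    z = rng.random(n) < expit(logit_psi)

    cnt_beta = np.asarray(params.count_opuntia)[s_idx]
    mu = np.exp(np.clip(params.count_intercept + cnt_beta * x + f_cnt, -LOGIT_CAP, LOGIT_CAP))
    phi = params.count_dispersion

    det_int = sites["camera_model"].map(dict(params.det_intercepts)).to_numpy(float)
    night_beta = np.asarray(params.night_opuntia)[s_idx]

    rows = []
    for season_val in sorted(sites["season"].unique()):
        dates = _season_dates(int(season_val), days)
        doy = np.array([d.timetuple().tm_yday for d in dates])
        lunar = _lunar_series(dates)
        idx = np.where(season == season_val)[0]
        temp = 24.0 + 6.0 * np.sin(2 * math.pi * (doy - 105) / 365.0) + rng.normal(
            0.0, 2.0, size=(len(idx), len(dates))
        )
        t_std = (temp - 24.0) / 4.0  # generation-scale standardization
        logit_p = np.clip(det_int[idx][:, None] + params.det_temp * t_std, -LOGIT_CAP, LOGIT_CAP)
        y = (rng.random(logit_p.shape) < expit(logit_p)) & z[idx][:, None]
        counts = rng.negative_binomial(
            phi, phi / (phi + mu[idx][:, None]), size=(len(idx), len(dates))
        )
        logit_pi = np.clip(
            params.night_intercept
            + night_beta[idx][:, None]
            + params.night_lunar * lunar[None, :]
            + params.night_opuntia_lunar * x[idx][:, None] * lunar[None, :],
            -LOGIT_CAP,
            LOGIT_CAP,
        )
        nights = rng.binomial(counts, expit(logit_pi))
        inactive = rng.random(y.shape) < inactive_prob
        for a, i in enumerate(idx):
            for b, dt in enumerate(dates):
                if inactive[a, b]:
                    rows.append(
                        dict(site_id=sites["site_id"].iat[i], date=dt.isoformat(),
                             detected=np.nan, count=np.nan, night_count=np.nan,
                             temp_c=round(float(temp[a, b]), 2), lunar_frac=round(float(lunar[b]), 4))
                    )
                else:
                    rows.append(
                        dict(site_id=sites["site_id"].iat[i], date=dt.isoformat(),
                             detected=int(y[a, b]), count=int(counts[a, b]),
                             night_count=int(nights[a, b]),
                             temp_c=round(float(temp[a, b]), 2), lunar_frac=round(float(lunar[b]), 4))
                    )
    obs = pd.DataFrame(rows)
    truth = {
        "z": z.astype(int).tolist(),
        "gp_field_occupancy": f_occ.tolist(),
        "gp_field_count": f_cnt.tolist(),
        "gp_field_night": f_night.tolist(),
        "exposure_mean": cov_mu,
        "exposure_sd": cov_sd,
        "site_ids": list(sites["site_id"]),
    }
    return obs, truth


def simulate_transects(
    design: StudyDesign, params: TrueParameters, seed: int = 0,
    return_truth: bool = False,
):
    """Simulate binned line-transect counts of cactus stands per square.

    True stand count per square and size class is Poisson(density); each
    stand sits at a uniform perpendicular distance within the truncation
    strip and is detected with half-normal probability exp(−x²/2σ²).
    With ``return_truth`` also returns a table of the true stand counts.
    """
    params.validate()
    rng = np.random.default_rng([seed, 404])
    breaks = np.asarray(design.bin_breaks_m, dtype=float)
    B = breaks[-1]
    rows = []
    truth_rows = []
    for sq in design.squares["square_id"]:
        for cls in ("S", "M", "L"):
            dens = float(params.ds_density[cls])
            sigma = float(params.ds_sigma[cls])
            n_true = rng.poisson(dens)
            if n_true > 0:
                xs = rng.uniform(0.0, B, n_true)
                if sigma == 0:
                    det = xs == 0.0
                else:
                    det = rng.random(n_true) < np.exp(-(xs**2) / (2.0 * sigma**2))
                cnt, _ = np.histogram(xs[det], breaks)
            else:
                cnt = np.zeros(len(breaks) - 1, dtype=int)
            for b in range(len(breaks) - 1):
                rows.append(
                    dict(square_id=sq, size_class=cls, bin_lo_m=breaks[b],
                         bin_hi_m=breaks[b + 1], count=int(cnt[b]),
                         transect_length_m=design.transect_length_m)
                )
            truth_rows.append(
                dict(square_id=sq, size_class=cls, n_true=int(n_true),
                     n_detected=int(cnt.sum()))
            )
    table = pd.DataFrame(rows)
    if return_truth:
        return table, pd.DataFrame(truth_rows)
    return table


def simulate_votes(
    true_labels: pd.DataFrame,
    params: TrueParameters,
    n_volunteers: int = 12,
    seed: int = 0,
    expert_fraction: float = 0.0,
) -> pd.DataFrame:
    """Draw volunteer vote vectors per image from the confusion structure.

    ``true_labels`` needs columns image_id, site_id, timestamp, true_label.
    Each image receives ``n_volunteers`` iid votes from the confusion row of
    its true label; a fraction of images additionally carries the (always
    correct) expert label.
    """
    params.validate()
    if n_volunteers < 1:
        raise ValueError("need at least one volunteer")
    rng = np.random.default_rng([seed, 505])
    conf = {k: dict(v) for k, v in params.confusion.items()}
    rows = []
    for _, img in true_labels.iterrows():
        tl = img["true_label"]
        if tl not in conf:
            raise ValueError(f"true label {tl!r} missing from confusion matrix")
        labels = list(conf[tl].keys())
        probs = np.asarray(list(conf[tl].values()), dtype=float)
        votes = rng.choice(labels, size=n_volunteers, p=probs)
        expert = tl if rng.random() < expert_fraction else None
        for v in range(n_volunteers):
            rows.append(
                dict(image_id=img["image_id"], site_id=img["site_id"],
                     timestamp=img["timestamp"], volunteer_id=f"vol{v + 1:03d}",
                     label=votes[v], expert_label=expert)
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    """One complete synthetic study: tables plus latent generative truth."""

    sites: pd.DataFrame
    observations: pd.DataFrame
    transects: pd.DataFrame
    votes: pd.DataFrame
    truth: dict

    def validate(self) -> None:
        pair = self.sites.sort_values("site_id").groupby("square_id")["opuntia_cover_pct"]
        for sq, vals in pair:
            v = vals.to_numpy()
            if not v[0] > v[1]:
                raise ValueError(f"square {sq}: site 1 cover not greater than site 2")
        unknown = set(self.observations["site_id"]) - set(self.sites["site_id"])
        if unknown:
            raise ValueError(f"observations reference unknown sites {sorted(unknown)[:5]}")
        z = np.asarray(self.truth["z"])
        if not np.isin(z, [0, 1]).all():
            raise ValueError("latent occupancy states must be 0/1")

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("sites", self.sites), ("observations", self.observations),
            ("transects", self.transects), ("votes", self.votes),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        p = out / "truth.json"
        p.write_text(json.dumps(self.truth, indent=1))
        paths["truth"] = p
        return paths


def generate_dataset(
    n_squares_s1: int = 46,
    n_squares_s2: int = 14,
    days: int = 60,
    seed: int = 0,
    params: TrueParameters | None = None,
    species: str = "impala",
    n_volunteers: int = 12,
    expert_fraction: float = 0.1,
    max_vote_images: int = 2000,
) -> SyntheticDataset:
    """Full synthetic study for one focal species, deterministic given seed.

    Vote vectors are generated for the images implied by the detection
    events (capped at ``max_vote_images``), each image carrying the focal
    species as its true label.
    """
    params = params or TrueParameters()
    design = generate_design(n_squares_s1, n_squares_s2, days, seed=seed)
    sites = simulate_site_covariates(design, params, seed=seed)
    obs, truth = simulate_observations(sites, params, days=days, seed=seed)
    transects = simulate_transects(design, params, seed=seed)

    det_days = obs[(obs["count"].fillna(0) > 0)]
    img_rows = []
    k = 0
    for _, r in det_days.iterrows():
        for e in range(int(r["count"])):
            if k >= max_vote_images:
                break
            img_rows.append(
                dict(image_id=f"img{k + 1:06d}", site_id=r["site_id"],
                     timestamp=f"{r['date']}T{(6 + 3 * e) % 24:02d}:30:00+03:00",
                     true_label=species)
            )
            k += 1
    votes = simulate_votes(
        pd.DataFrame(img_rows), params, n_volunteers=n_volunteers,
        seed=seed, expert_fraction=expert_fraction,
    ) if img_rows else pd.DataFrame(
        columns=["image_id", "site_id", "timestamp", "volunteer_id", "label", "expert_label"]
    )

    truth = {**truth, "params": params.to_json(), "species": species, "seed": seed}
    ds = SyntheticDataset(sites, obs, transects, votes, truth)
    ds.validate()
    return ds
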