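"""End-to-end orchestration: simulate → consensus → distance → adjust → fit → report.

A run directory accumulates the stage artefacts plus ``manifest.json``
recording seeds, parameter settings and SHA-256 hashes of every stage's
inputs; a rerun skips stages whose inputs are unchanged and whose outputs
exist. Configuration is a flat TOML file with one section per stage; any
value can be overridden from the command line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import classify_vote_table
from .dag import bundled_habitat_dag, load_dag, total_effect_sets
from .distance import (SIZE_CLASSES, bin_detection_probs, fit_distance_model,
                       volume_from_counts)
from .models import ModelSpec, build_model_data, sample_posterior
from .reporting import effect_matrix, marginal_effect_curve, summarize_effect
from .synthetic import TrueParameters, generate_dataset
from .validate import validate_tables

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("invade")

EXPOSURES = {"site_cover": "opuntia_cover_pct", "square_volume": "total_vol_m3"}


@dataclass
class PipelineConfig:
    out_dir: Path = Path("run")
    seed: int = 0
    species: str = "impala"
    # simulate
    n_squares_s1: int = 20
    n_squares_s2: int = 8
    days: int = 30
    n_volunteers: int = 12
    expert_fraction: float = 0.1
    # consensus
    species_threshold: float = 0.66
    entropy_max: float = 1.0
    entropy_base: str = "nat"
    # fit
    chains: int = 2
    warmup: int = 500
    iters: int = 500
    responses: tuple[str, ...] = ("occupancy", "count", "night")
    scales: tuple[str, ...] = ("site_cover", "square_volume")
    use_native_plants: bool = False
    # stage toggles
    stages: tuple[str, ...] = ("simulate", "consensus", "distance", "adjust", "fit", "report")
    dag_path: Path | None = None

    @property
    def native_covariates(self) -> tuple[str, ...]:
        return ("grass_pct", "shrub_pct", "forb_pct", "succulent_pct", "tree_count")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat TOML config; unknown keys are rejected."""
    raw = tomllib.loads(Path(path).read_text())
    flat: dict = {}
    for k, val in raw.items():
        if isinstance(val, dict):
            flat.update(val)
        else:
            flat[k] = val
    cfg = PipelineConfig()
    for k, val in flat.items():
        if not hasattr(cfg, k):
            raise KeyError(f"unknown config key {k!r}")
        default = getattr(cfg, k)
        if isinstance(default, tuple):
            val = tuple(val)
        elif isinstance(default, Path) or k.endswith("_path") or k.endswith("_dir"):
            val = Path(val)
        setattr(cfg, k, val)
    return cfg


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = (
            json.loads(self.path.read_text()) if self.path.exists() else {"stages": {}}
        )
        self.data["version"] = __version__

    def stage_fresh(self, name: str, inputs: list[Path], outputs: list[Path], params: dict) -> bool:
        rec = self.data["stages"].get(name)
        if rec is None:
            return False
        if rec["params"] != {k: str(v) for k, v in params.items()}:
            return False
        if rec["inputs"] != {str(p): _sha(p) for p in inputs if p.exists()}:
            return False
        return all(Path(o).exists() for o in rec["outputs"])

    def record(self, name: str, inputs: list[Path], outputs: list[Path], params: dict, status="ok", seconds=0.0):
        self.data["stages"][name] = {
            "inputs": {str(p): _sha(p) for p in inputs if p.exists()},
            "outputs": [str(o) for o in outputs],
            "params": {k: str(v) for k, v in params.items()},
            "status": status,
            "wall_s": round(seconds, 2),
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages in dependency order; returns the run dir.

    A stage failure is recorded in the manifest and halts downstream stages.
    Reruns with unchanged inputs skip up-to-date stages.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = _Manifest(out)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")

    def stage(name, inputs, outputs, params, fn):
        if name not in cfg.stages:
            return
        inputs = [Path(p) for p in inputs]
        outputs = [Path(p) for p in outputs]
        if man.stage_fresh(name, inputs, outputs, params):
            log.info("stage %s: up to date, skipped", name)
            return
        log.info("stage %s: running (seed=%s)", name, cfg.seed)
        t0 = time.time()
        try:
            fn()
        except Exception:
            man.record(name, inputs, outputs, params, status="failed", seconds=time.time() - t0)
            raise
        man.record(name, inputs, outputs, params, seconds=time.time() - t0)
        log.info("stage %s: done in %.1fs", name, time.time() - t0)

    sites_p = out / "sites.csv"
    obs_p = out / "observations.csv"
    tran_p = out / "transects.csv"
    votes_p = out / "votes.csv"
    det_p = out / "detections.csv"
    sq_p = out / "square_opuntia.csv"
    cov_p = out / "covariates.json"
    eff_p = out / "effects.csv"

    # --- simulate ---
    def do_simulate():
        ds = generate_dataset(
            n_squares_s1=cfg.n_squares_s1, n_squares_s2=cfg.n_squares_s2,
            days=cfg.days, seed=cfg.seed, species=cfg.species,
            n_volunteers=cfg.n_volunteers, expert_fraction=cfg.expert_fraction,
        )
        ds.write(out)
        report = validate_tables(
            {"sites": sites_p, "observations": obs_p, "transects": tran_p, "votes": votes_p}
        )
        if len(report):
            raise RuntimeError(f"synthetic tables failed validation:\n{report}")

    stage("simulate", [], [sites_p, obs_p, tran_p, votes_p],
          {"seed": cfg.seed, "squares": (cfg.n_squares_s1, cfg.n_squares_s2),
           "days": cfg.days, "species": cfg.species}, do_simulate)

    # --- consensus ---
    def do_consensus():
        votes = pd.read_csv(votes_p)
        res = classify_vote_table(
            votes, species_threshold=cfg.species_threshold,
            entropy_max=cfg.entropy_max, base=cfg.entropy_base,
        )
        meta = votes.groupby("image_id").first()[["site_id", "timestamp"]]
        det = res.join(meta, on="image_id")
        rows = []
        for _, r in det.iterrows():
            for sp in str(r["species"]).split(";"):
                if sp and sp != "nan":
                    rows.append({"image_id": r["image_id"], "site_id": r["site_id"],
                                 "timestamp": r["timestamp"], "species": sp,
                                 "status": r["status"]})
        pd.DataFrame(rows, columns=["image_id", "site_id", "timestamp", "species", "status"]).to_csv(det_p, index=False)

    stage("consensus", [votes_p], [det_p],
          {"threshold": cfg.species_threshold, "entropy_max": cfg.entropy_max},
          do_consensus)

    # --- distance ---
    def do_distance():
        tr = pd.read_csv(tran_p)
        fit = fit_distance_model(tr, chains=cfg.chains, warmup=cfg.warmup,
                                 iters=cfg.iters, seed=cfg.seed)
        breaks = np.append(np.sort(tr["bin_lo_m"].unique()), tr["bin_hi_m"].max())
        rows = []
        for sq, grp in tr.groupby("square_id"):
            rec = {"square_id": sq}
            length = float(grp["transect_length_m"].iloc[0])
            lam_by_cls = {}
            for cls in SIZE_CLASSES:
                y = grp.loc[grp["size_class"] == cls, "count"].sum()
                # Horvitz-Thompson per-square abundance given posterior sigma
                sig_draws = fit.draws[cls][:, 0]
                pbar = np.array([bin_detection_probs(breaks, s)[1] for s in sig_draws[::10]])
                n_draws = y / pbar
                lam_by_cls[cls] = n_draws
                rec[f"lambda_{cls}"] = float(n_draws.mean())
                rec[f"lambda_{cls}_q5"], rec[f"lambda_{cls}_q95"] = np.quantile(n_draws, [0.05, 0.95])
            vols = volume_from_counts(lam_by_cls["S"], lam_by_cls["M"], lam_by_cls["L"])
            rec["vol_m3"] = float(np.mean(vols))
            rec["vol_per_m"] = rec["vol_m3"] / length
            rec["total_vol_m3"] = rec["vol_per_m"] * 500.0
            rec["vol_m3_q5"], rec["vol_m3_q95"] = np.quantile(vols, [0.05, 0.95])
            rows.append(rec)
        pd.DataFrame(rows).to_csv(sq_p, index=False)

    stage("distance", [tran_p], [sq_p], {"seed": cfg.seed, "chains": cfg.chains}, do_distance)

    # --- adjust (back-door covariate selection) ---
    def do_adjust():
        dag = load_dag(cfg.dag_path) if cfg.dag_path else bundled_habitat_dag()
        sets = total_effect_sets(dag, dag.exposure or "opuntia", dag.outcome or "habitat_use")
        if not sets:
            raise RuntimeError("no observed back-door adjustment set exists for the DAG")
        mapping = {"livestock": "livestock_prop", "dist_river": "dist_river_m",
                   "dist_road": "dist_road_m"}
        chosen = sorted(sets[0])
        covs = [mapping.get(n, n) for n in chosen]
        cov_p.write_text(json.dumps({
            "adjustment_set": chosen,
            "covariate_columns": covs,
            "with_native_plants": covs + list(cfg.native_covariates),
        }, indent=1))

    stage("adjust", [cfg.dag_path] if cfg.dag_path else [], [cov_p], {"dag": cfg.dag_path or "bundled"}, do_adjust)

    # --- fit ---
    draws_dir = out / "draws"

    def do_fit():
        draws_dir.mkdir(exist_ok=True)
        sites = pd.read_csv(sites_p)
        obs = pd.read_csv(obs_p)
        covs = json.loads(cov_p.read_text())
        columns = covs["with_native_plants" if cfg.use_native_plants else "covariate_columns"]
        sq = pd.read_csv(sq_p)
        sites = sites.merge(sq[["square_id", "total_vol_m3"]], on="square_id", how="left")
        for scale in cfg.scales:
            exposure = EXPOSURES[scale]
            for resp in cfg.responses:
                spec = ModelSpec(response=resp, exposure=exposure,
                                 covariates=tuple(columns), gp=True)
                data = build_model_data(sites, obs, spec)
                draws = sample_posterior(spec, data, chains=cfg.chains,
                                         warmup=cfg.warmup, iters=cfg.iters,
                                         seed=cfg.seed, check=False)
                tag = f"{cfg.species}_{scale}_{resp}"
                draws.to_frame().to_csv(draws_dir / f"{tag}.csv", index=False)
                (draws_dir / f"{tag}.json").write_text(json.dumps({
                    "species": cfg.species, "scale": scale, "response": resp,
                    "exposure": exposure, "covariates": columns,
                    "seed": cfg.seed, "chains": cfg.chains,
                    "warmup": cfg.warmup, "iters": cfg.iters,
                    "scaling": {k: list(v) for k, v in draws.scaling.items()},
                    "divergences": draws.divergences.tolist(),
                }, indent=1))

    stage("fit", [sites_p, obs_p, sq_p, cov_p], [draws_dir],
          {"seed": cfg.seed, "chains": cfg.chains, "warmup": cfg.warmup,
           "iters": cfg.iters, "scales": cfg.scales, "responses": cfg.responses,
           "native": cfg.use_native_plants}, do_fit)

    # --- report ---
    def do_report():
        summaries = []
        rows = []
        for scale in cfg.scales:
            for resp in cfg.responses:
                tag = f"{cfg.species}_{scale}_{resp}"
                df = pd.read_csv(draws_dir / f"{tag}.csv")
                meta = json.loads((draws_dir / f"{tag}.json").read_text())
                names = list(dict.fromkeys(df["parameter"]))
                C = df["chain"].nunique()
                I = df["iter"].nunique()
                arr = (df.pivot_table(index=["chain", "iter"], columns="parameter",
                                      values="value", sort=False)
                       .reindex(columns=names).to_numpy().reshape(C, I, len(names)))
                from .models import PosteriorDraws
                d = PosteriorDraws(arr, names, 0, meta["seed"],
                                   np.asarray(meta["divergences"]), np.zeros(C),
                                   spec=ModelSpec(response=resp, exposure=meta["exposure"],
                                                  covariates=tuple(meta["covariates"])),
                                   scaling={k: tuple(v) for k, v in meta["scaling"].items()})
                seasons = sorted({int(n.split(",s")[1][:-1]) for n in names if n.startswith("beta[")})
                for season in seasons:
                    s = summarize_effect(d, cfg.species, season, scale)
                    summaries.append(s)
                    ci = {f"ci{int(lv)}_lo": lo for lv, lo, hi in s.intervals}
                    ci.update({f"ci{int(lv)}_hi": hi for lv, lo, hi in s.intervals})
                    rows.append({"species": cfg.species, "season": season,
                                 "scale": scale, "model": resp,
                                 "p_positive": s.p_positive, **ci})
        pd.DataFrame(rows).to_csv(eff_p, index=False)
        mat = effect_matrix(summaries)
        mat.to_csv(out / "effect_matrix.csv")

    stage("report", [draws_dir], [eff_p], {"species": cfg.species}, do_report)
    return out
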