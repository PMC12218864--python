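"""Consensus species classification from volunteer votes.

Camera-trap images are first screened with machine detector scores, then shown
to ≥12 volunteers each. A species is accepted for an image when at least 66%
of the volunteers voted for it; images whose vote distribution has Shannon
entropy above 1 are discarded as too ambiguous; an expert label, where one
exists, overrides the volunteers entirely. The module also audits consensus
accuracy against expert-labelled images (sensitivity/specificity per species)
and aggregates accepted detections into per-site daily detection histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusStatus",
    "ConsensusResult",
    "filter_detector_scores",
    "shannon_entropy",
    "consensus_classify",
    "classification_accuracy",
    "build_detection_histories",
]

DEFAULT_SPECIES_THRESHOLD = 0.66
DEFAULT_ENTROPY_MAX = 1.0
DEFAULT_ANIMAL_THRESHOLD = 0.98
DEFAULT_HUMAN_THRESHOLD = 0.10


class ConsensusStatus(str, Enum):
    CONSENSUS = "consensus"
    NO_CONSENSUS = "no_consensus"
    DISCARDED_ENTROPY = "discarded_entropy"
    EXPERT = "expert"


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of consensus classification for one image."""

    image_id: str
    species: frozenset[str]
    status: ConsensusStatus
    entropy: float


def filter_detector_scores(
    records: pd.DataFrame,
    animal_thr: float = DEFAULT_ANIMAL_THRESHOLD,
    human_thr: float = DEFAULT_HUMAN_THRESHOLD,
    confirmed_human: Iterable[str] = (),
) -> pd.DataFrame:
    """Screen detector scores; return records with retention/screening flags.

    Records with ``animal_score >= animal_thr`` are auto-retained. Records
    whose human or vehicle score is ``>= human_thr`` are flagged for manual
    screening and dropped when their image id appears in ``confirmed_human``.
    Both thresholds are inclusive.

    Returns a copy with boolean columns ``needs_screening`` and ``retained``.
    """
    req = {"image_id", "animal_score", "human_score", "vehicle_score"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"detector score table missing columns: {sorted(missing)}")
    scores = records[["animal_score", "human_score", "vehicle_score"]].to_numpy(float)
    if np.any(scores < 0) or np.any(scores > 1) or np.any(~np.isfinite(scores)):
        raise ValueError("detector scores must lie in [0, 1]")

    out = records.copy()
    confirmed = set(confirmed_human)
    out["needs_screening"] = (out["human_score"] >= human_thr) | (
        out["vehicle_score"] >= human_thr
    )
    is_confirmed = out["image_id"].isin(confirmed)
    out["retained"] = (out["animal_score"] >= animal_thr) & ~is_confirmed
    return out[~is_confirmed | ~out["needs_screening"]].reset_index(drop=True)


def shannon_entropy(dist: Mapping[str, int], base: str | float = "nat") -> float:
    """Shannon entropy of a vote-count distribution.

    H = −Σ q log(q) over labels with nonzero counts, q = count / total.
    ``base`` is ``"nat"`` (natural log, default), ``"bit"``/2, or any float.
    """
    counts = np.asarray([c for c in dist.values() if c > 0], dtype=float)
    if np.any(np.asarray(list(dist.values())) < 0):
        raise ValueError("vote counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an empty vote distribution")
    q = counts / total
    h = float(-(q * np.log(q)).sum())
    if base in ("nat", "e", math.e):
        return h
    if base in ("bit", "bits", 2):
        return h / math.log(2.0)
    return h / math.log(float(base))


def consensus_classify(
    votes: Mapping[str, int],
    n_volunteers: int | None = None,
    species_threshold: float = DEFAULT_SPECIES_THRESHOLD,
    entropy_max: float = DEFAULT_ENTROPY_MAX,
    base: str | float = "nat",
    expert_label: str | Sequence[str] | None = None,
    image_id: str = "",
    empty_label: str = "empty",
) -> ConsensusResult:
    """Classify one image from its volunteer vote distribution.

    ``votes`` maps label -> number of volunteers who tagged that label on the
    image (an "empty" vote is a label like any other). A species is declared
    present when its votes / total volunteers >= ``species_threshold``
    (inclusive). If the vote entropy exceeds ``entropy_max`` (strictly) the
    image is discarded regardless of threshold. An expert label overrides
    everything.

    ``n_volunteers`` defaults to the total number of votes; pass it explicitly
    for multi-species images where one volunteer may tag several species.
    """
    if not (0.0 < species_threshold <= 1.0):
        raise ValueError(f"species_threshold must lie in (0, 1], got {species_threshold}")
    if sum(votes.values()) < 1:
        raise ValueError("at least one vote is required")

    h = shannon_entropy(votes, base=base)

    if expert_label is not None:
        labels = (
            frozenset([expert_label])
            if isinstance(expert_label, str)
            else frozenset(expert_label)
        )
        return ConsensusResult(image_id, labels - {empty_label}, ConsensusStatus.EXPERT, h)

    if h > entropy_max:
        return ConsensusResult(image_id, frozenset(), ConsensusStatus.DISCARDED_ENTROPY, h)

    total = n_volunteers if n_volunteers is not None else sum(votes.values())
    present = frozenset(
        label
        for label, c in votes.items()
        if label != empty_label and c / total >= species_threshold
    )
    empty_consensus = votes.get(empty_label, 0) / total >= species_threshold
    if present or empty_consensus:
        return ConsensusResult(image_id, present, ConsensusStatus.CONSENSUS, h)
    return ConsensusResult(image_id, frozenset(), ConsensusStatus.NO_CONSENSUS, h)


def classify_vote_table(
    votes: pd.DataFrame,
    species_threshold: float = DEFAULT_SPECIES_THRESHOLD,
    entropy_max: float = DEFAULT_ENTROPY_MAX,
    base: str | float = "nat",
) -> pd.DataFrame:
    """Apply :func:`consensus_classify` to a long-format vote table.

    Expects columns ``image_id, volunteer_id, label`` and optionally
    ``expert_label`` (non-null on expert-reviewed images). Returns one row per
    image with ``species`` (semicolon-joined), ``status`` and ``entropy``.
    """
    rows = []
    has_expert = "expert_label" in votes.columns
    for image_id, grp in votes.groupby("image_id", sort=True):
        counts = grp["label"].value_counts().to_dict()
        expert = None
        if has_expert:
            vals = grp["expert_label"].dropna().unique()
            if len(vals):
                expert = list(vals)
        res = consensus_classify(
            counts,
            n_volunteers=grp["volunteer_id"].nunique(),
            species_threshold=species_threshold,
            entropy_max=entropy_max,
            base=base,
            expert_label=expert,
            image_id=str(image_id),
        )
        rows.append(
            {
                "image_id": res.image_id,
                "species": ";".join(sorted(res.species)),
                "status": res.status.value,
                "entropy": res.entropy,
            }
        )
    return pd.DataFrame(rows)


def classification_accuracy(
    consensus: pd.DataFrame,
    expert: pd.DataFrame,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-species sensitivity and specificity of consensus vs expert labels.

    ``consensus``: image_id, species (semicolon-joined), status. ``expert``:
    image_id, species. Images whose consensus status is ``expert`` are
    excluded (no self-comparison). Presence/absence is evaluated per image.
    Species with zero expert positives get sensitivity NaN.
    """
    if expert.empty:
        raise ValueError("expert subset is empty")
    cons = consensus[consensus["status"] != ConsensusStatus.EXPERT.value]
    merged = cons.merge(expert, on="image_id", suffixes=("_cons", "_exp"))
    if merged.empty:
        raise ValueError("no overlap between consensus images and expert subset")

    cons_sets = merged["species_cons"].fillna("").map(
        lambda s: set(x for x in str(s).split(";") if x)
    )
    exp_sets = merged["species_exp"].fillna("").map(
        lambda s: set(x for x in str(s).split(";") if x)
    )
    if species is None:
        species = sorted(set().union(*cons_sets) | set().union(*exp_sets))

    out = []
    for sp in species:
        in_cons = np.array([sp in s for s in cons_sets])
        in_exp = np.array([sp in s for s in exp_sets])
        tp = int((in_cons & in_exp).sum())
        fn = int((~in_cons & in_exp).sum())
        tn = int((~in_cons & ~in_exp).sum())
        fp = int((in_cons & ~in_exp).sum())
        sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        out.append(
            {"species": sp, "sensitivity": sens, "specificity": spec,
             "tp": tp, "fn": fn, "tn": tn, "fp": fp}
        )
    return pd.DataFrame(out)


def build_detection_histories(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    species: str,
    night_labeler: Callable[[pd.Timestamp, float, float], bool],
    timezone_offset_hours: float = 3.0,
    livestock_label: str = "livestock",
) -> pd.DataFrame:
    """Aggregate consensus detections into a per-site daily observation set.

    Parameters
    ----------
    detections
        Accepted detections: site_id, timestamp, species.
    deployments
        One row per site: site_id, start (date), end (date, inclusive),
        latitude, longitude.
    species
        Focal species to build the history for.
    night_labeler
        ``f(timestamp, lat, lon) -> bool``; typically a closure over
        :func:`invade.solar.is_night`.

    Returns
    -------
    DataFrame with site_id, date, detected, count, night_count per active
    site-day, plus a per-site ``livestock_prop`` column (proportion of active
    days with >=1 livestock detection).

    Raises
    ------
    ValueError
        If any detection falls outside its site's deployment interval.
    """
    dep = deployments.set_index("site_id")
    det = detections.copy()
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    local = det["timestamp"] + pd.Timedelta(hours=timezone_offset_hours)
    det["date"] = local.dt.date

    for _, row in det.iterrows():
        site = row["site_id"]
        if site not in dep.index:
            raise ValueError(f"detection references unknown site {site!r}")
        d0, d1 = pd.Timestamp(dep.loc[site, "start"]).date(), pd.Timestamp(
            dep.loc[site, "end"]
        ).date()
        if not (d0 <= row["date"] <= d1):
            raise ValueError(
                f"detection {row.get('image_id', row['timestamp'])} at site {site!r} "
                f"on {row['date']} lies outside deployment [{d0}, {d1}]"
            )

    rows = []
    live_prop = {}
    for site, drow in deployments.set_index("site_id").iterrows():
        d0 = pd.Timestamp(drow["start"]).date()
        d1 = pd.Timestamp(drow["end"]).date()
        lat, lon = float(drow["latitude"]), float(drow["longitude"])
        site_det = det[det["site_id"] == site]
        sp_det = site_det[site_det["species"] == species]
        lv_days = set(site_det.loc[site_det["species"] == livestock_label, "date"])
        n_days = (d1 - d0).days + 1
        live_prop[site] = len(lv_days) / n_days if n_days else float("nan")
        for k in range(n_days):
            day = d0 + timedelta(days=k)
            todays = sp_det[sp_det["date"] == day]
            cnt = len(todays)
            night = sum(
                1 for ts in todays["timestamp"] if night_labeler(ts, lat, lon)
            )
            rows.append(
                {
                    "site_id": site,
                    "date": day,
                    "detected": int(cnt > 0),
                    "count": cnt,
                    "night_count": night,
                }
            )
    obs = pd.DataFrame(rows)
    obs["livestock_prop"] = obs["site_id"].map(live_prop)
    return obs
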