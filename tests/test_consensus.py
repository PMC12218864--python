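"""Consensus classification, accuracy audit and detection histories."""

import math
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invade.consensus import (ConsensusStatus, build_detection_histories,
                              classification_accuracy, classify_vote_table,
                              consensus_classify, filter_detector_scores,
                              shannon_entropy)
from invade.synthetic import TrueParameters, simulate_votes


# --- shannon entropy ---------------------------------------------------------

@pytest.mark.parametrize(
    "dist,base,expected",
    [
        ({"impala": 12}, "nat", 0.0),
        ({"impala": 6, "empty": 6}, "nat", math.log(2)),
        ({"a": 4, "b": 4, "c": 4}, "nat", math.log(3)),
        ({"a": 6, "b": 6}, 2, 1.0),
        ({"elephant": 8, "empty": 4}, "nat", -(2 / 3) * math.log(2 / 3) - (1 / 3) * math.log(1 / 3)),
    ],
)
def test_entropy_closed_forms(dist, base, expected):
    assert shannon_entropy(dist, base) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_empty():
    with pytest.raises(ValueError):
        shannon_entropy({})
    with pytest.raises(ValueError):
        shannon_entropy({"a": 0})


@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=8).filter(
        lambda c: sum(c) > 0
    )
)
@settings(max_examples=100, deadline=None)
def test_entropy_bounds_and_permutation_invariance(counts):
    dist = {f"l{i}": c for i, c in enumerate(counts)}
    h = shannon_entropy(dist)
    nonzero = sum(1 for c in counts if c > 0)
    assert -1e-12 <= h <= math.log(max(nonzero, 1)) + 1e-12
    perm = {f"l{i}": c for i, c in enumerate(reversed(counts))}
    assert shannon_entropy(perm) == pytest.approx(h, abs=1e-12)


# --- consensus rule ----------------------------------------------------------

def test_consensus_eight_of_twelve_accepted():
    # 8/12 = 0.667 >= 0.66 and H = 0.6365 nats <= 1
    res = consensus_classify({"elephant": 8, "empty": 4})
    assert res.species == frozenset({"elephant"})
    assert res.status == ConsensusStatus.CONSENSUS
    assert res.entropy == pytest.approx(0.6365, abs=5e-4)


def test_consensus_three_way_split_discarded_by_entropy():
    res = consensus_classify({"a": 4, "b": 4, "c": 4})
    assert res.status == ConsensusStatus.DISCARDED_ENTROPY
    assert res.species == frozenset()
    assert res.entropy == pytest.approx(math.log(3), abs=1e-9)


def test_expert_label_overrides_votes():
    res = consensus_classify({"impala": 2, "kudu": 10}, expert_label="leopard")
    assert res.status == ConsensusStatus.EXPERT
    assert res.species == frozenset({"leopard"})


def test_threshold_boundary_inclusive():
    # 66 of 100 volunteers: exactly 0.66 -> present
    res = consensus_classify({"impala": 66, "empty": 34}, entropy_max=10.0)
    assert "impala" in res.species
    res = consensus_classify({"impala": 65, "empty": 35}, entropy_max=10.0)
    assert res.status == ConsensusStatus.NO_CONSENSUS


def test_threshold_validation():
    with pytest.raises(ValueError):
        consensus_classify({"a": 1}, species_threshold=0.0)
    with pytest.raises(ValueError):
        consensus_classify({"a": 1}, species_threshold=1.2)
    with pytest.raises(ValueError):
        consensus_classify({})


def test_multi_species_image_passes_for_both():
    # one volunteer may tag several species: denominator is volunteers
    res = consensus_classify({"impala": 9, "zebra": 9, "empty": 1}, n_volunteers=12,
                             entropy_max=10.0)
    assert res.species == frozenset({"impala", "zebra"})


@given(st.dictionaries(st.sampled_from(["a", "b", "c", "e"]),
                       st.integers(min_value=0, max_value=12), min_size=1).filter(
    lambda d: sum(d.values()) > 0))
@settings(max_examples=100, deadline=None)
def test_adding_a_vote_never_removes_the_species(votes):
    before = consensus_classify(dict(votes), entropy_max=math.inf)
    more = dict(votes)
    more["a"] = more.get("a", 0) + 1
    after = consensus_classify(more, entropy_max=math.inf)
    if "a" in before.species:
        assert "a" in after.species


# --- detector-score screening ------------------------------------------------

def test_detector_score_thresholds_inclusive():
    df = pd.DataFrame(
        {
            "image_id": ["a", "b", "c", "d"],
            "animal_score": [0.98, 0.979, 0.999, 0.2],
            "human_score": [0.0, 0.0, 0.10, 0.5],
            "vehicle_score": [0.0, 0.0, 0.0, 0.0],
        }
    )
    out = filter_detector_scores(df, confirmed_human=["d"])
    kept = dict(zip(out["image_id"], out["retained"]))
    assert kept["a"] and kept["c"]
    assert not kept["b"]  # 0.979 < 0.98: not auto-retained
    assert "d" not in set(out["image_id"])  # confirmed human dropped
    assert bool(out.loc[out["image_id"] == "c", "needs_screening"].iloc[0])


def test_detector_scores_outside_unit_interval_rejected():
    df = pd.DataFrame(
        {"image_id": ["a"], "animal_score": [1.2], "human_score": [0.0],
         "vehicle_score": [0.0]}
    )
    with pytest.raises(ValueError):
        filter_detector_scores(df)


# --- accuracy audit ----------------------------------------------------------

def test_accuracy_perfect_agreement():
    cons = pd.DataFrame(
        {"image_id": ["i1", "i2", "i3"], "species": ["impala", "", "kudu"],
         "status": ["consensus"] * 3}
    )
    exp = pd.DataFrame({"image_id": ["i1", "i2", "i3"], "species": ["impala", "", "kudu"]})
    acc = classification_accuracy(cons, exp).set_index("species")
    assert (acc["sensitivity"].dropna() == 1.0).all()
    assert (acc["specificity"] == 1.0).all()


def test_accuracy_definition_arithmetic():
    # TP=97, FN=3, TN=998, FP=2 -> sens 0.97, spec 0.998
    n = 97 + 3 + 998 + 2
    ids = [f"i{k}" for k in range(n)]
    cons_sp = ["impala"] * 97 + [""] * 3 + [""] * 998 + ["impala"] * 2
    exp_sp = ["impala"] * 97 + ["impala"] * 3 + [""] * 998 + [""] * 2
    cons = pd.DataFrame({"image_id": ids, "species": cons_sp, "status": ["consensus"] * n})
    exp = pd.DataFrame({"image_id": ids, "species": exp_sp})
    acc = classification_accuracy(cons, exp, species=["impala"]).iloc[0]
    assert acc["sensitivity"] == pytest.approx(0.97)
    assert acc["specificity"] == pytest.approx(0.998)


def test_accuracy_zero_expert_positives_gives_missing_sensitivity():
    cons = pd.DataFrame({"image_id": ["i1", "i2"], "species": ["", ""],
                         "status": ["consensus"] * 2})
    exp = pd.DataFrame({"image_id": ["i1", "i2"], "species": ["", ""]})
    acc = classification_accuracy(cons, exp, species=["leopard"]).iloc[0]
    assert np.isnan(acc["sensitivity"])
    assert acc["specificity"] == 1.0


def test_accuracy_excludes_expert_status_images():
    cons = pd.DataFrame(
        {"image_id": ["i1", "i2"], "species": ["impala", "impala"],
         "status": ["expert", "consensus"]}
    )
    exp = pd.DataFrame({"image_id": ["i1", "i2"], "species": ["impala", "impala"]})
    acc = classification_accuracy(cons, exp, species=["impala"]).iloc[0]
    assert acc["tp"] == 1  # i1 not self-compared


# --- vote-table pipeline -----------------------------------------------------

def test_identity_confusion_yields_perfect_consensus():
    conf = {sp: {sp: 1.0} for sp in ["impala", "kudu", "empty", "livestock"]}
    params = TrueParameters(confusion=conf)
    imgs = pd.DataFrame(
        {
            "image_id": [f"img{k}" for k in range(60)],
            "site_id": "s1",
            "timestamp": "2021-02-01T08:00:00+03:00",
            "true_label": ["impala", "kudu", "livestock"] * 20,
        }
    )
    votes = simulate_votes(imgs, params, n_volunteers=12, seed=0)
    res = classify_vote_table(votes)
    assert (res["status"] == "consensus").all()
    assert (res["entropy"] == 0).all()
    merged = res.merge(imgs, on="image_id")
    assert (merged["species"] == merged["true_label"]).all()


def test_status_partition_conservation():
    params = TrueParameters()
    imgs = pd.DataFrame(
        {
            "image_id": [f"img{k}" for k in range(200)],
            "site_id": "s1",
            "timestamp": "2021-02-01T08:00:00+03:00",
            "true_label": "impala",
        }
    )
    votes = simulate_votes(imgs, params, n_volunteers=12, seed=1, expert_fraction=0.1)
    res = classify_vote_table(votes)
    counts = res["status"].value_counts()
    assert counts.sum() == 200  # every uploaded image lands in exactly one bin
    assert set(counts.index) <= {"consensus", "no_consensus", "discarded_entropy", "expert"}


# --- detection histories -----------------------------------------------------

def _mk_deployments():
    return pd.DataFrame(
        {
            "site_id": ["s1"],
            "start": ["2021-02-01"],
            "end": ["2021-02-10"],
            "latitude": [0.3],
            "longitude": [36.9],
        }
    )


def test_histories_counting_and_night_split():
    det = pd.DataFrame(
        {
            "site_id": ["s1"] * 3,
            "timestamp": [
                "2021-02-03T10:00:00+00:00",  # day
                "2021-02-03T12:00:00+00:00",  # day
                "2021-02-03T19:00:00+00:00",  # after dusk (22:00 local)
            ],
            "species": ["impala"] * 3,
        }
    )
    from invade.solar import is_night

    obs = build_detection_histories(det, _mk_deployments(), "impala", is_night)
    assert len(obs) == 10
    day3 = obs[obs["date"].astype(str) == "2021-02-03"].iloc[0]
    assert day3["count"] == 3 and day3["night_count"] == 1 and day3["detected"] == 1
    assert obs["count"].sum() == 3


def test_histories_empty_deployment():
    det = pd.DataFrame(columns=["site_id", "timestamp", "species"])
    from invade.solar import is_night

    obs = build_detection_histories(det, _mk_deployments(), "impala", is_night)
    assert len(obs) == 10
    assert (obs["detected"] == 0).all() and (obs["count"] == 0).all()


def test_histories_out_of_deployment_detection_errors():
    det = pd.DataFrame(
        {"site_id": ["s1"], "timestamp": ["2021-03-15T08:00:00+00:00"],
         "species": ["impala"]}
    )
    from invade.solar import is_night

    with pytest.raises(ValueError, match="outside deployment"):
        build_detection_histories(det, _mk_deployments(), "impala", is_night)


def test_histories_livestock_proportion():
    det = pd.DataFrame(
        {
            "site_id": ["s1", "s1"],
            "timestamp": ["2021-02-02T09:00:00+00:00", "2021-02-05T09:00:00+00:00"],
            "species": ["livestock", "livestock"],
        }
    )
    from invade.solar import is_night

    obs = build_detection_histories(det, _mk_deployments(), "impala", is_night)
    assert obs["livestock_prop"].iloc[0] == pytest.approx(0.2)  # 2 of 10 days
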