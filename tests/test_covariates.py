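"""Network-state statistics and design-matrix construction."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_events
from premnet import covariates as cov
from premnet.covariates import (
    MODEL_REGISTRY,
    EventView,
    NetworkState,
    bin_experience,
    build_design,
    common_associates,
    repeated_partner_count,
)

CLASSES = {"a": "A", "b": "A", "c": "A", "d": "B", "e": "B", "f": "B"}


def random_history(rng, n=60, ids=tuple(CLASSES)):
    rows = []
    for _ in range(n):
        s, t = rng.choice(ids, size=2, replace=False)
        rows.append((s, t))
    return rows


def apply_all(rows):
    state = NetworkState(CLASSES)
    for s, t in rows:
        state.apply(s, t)
    return state


class TestBinExperience:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "none"), (1, "low"), (5, "low"), (6, "high"), (40, "high")],
    )
    def test_bins(self, count, expected):
        assert bin_experience(count) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_experience(-1)


class TestRepeatedPartnerCount:
    def test_empty_history(self):
        state = NetworkState(CLASSES)
        assert repeated_partner_count(state, "a", "same") == 0
        assert repeated_partner_count(state, "a", "diff") == 0

    def test_one_repeated_same_class_partner(self):
        state = apply_all([("a", "b"), ("b", "a"), ("a", "d")])
        assert repeated_partner_count(state, "a", "same") == 1  # b, twice
        assert repeated_partner_count(state, "a", "diff") == 0  # d only once

    def test_matches_bruteforce(self, rng):
        rows = random_history(rng)
        state = apply_all(rows)
        for focal in CLASSES:
            partners = {}
            for s, t in rows:
                if focal in (s, t):
                    other = t if s == focal else s
                    partners[other] = partners.get(other, 0) + 1
            for flt in ("same", "diff"):
                expected = sum(
                    1
                    for p, n in partners.items()
                    if n >= 2 and (CLASSES[p] == CLASSES[focal]) == (flt == "same")
                )
                assert repeated_partner_count(state, focal, flt) == expected


class TestCommonAssociates:
    def test_no_shared_partners(self):
        state = apply_all([("a", "b")])
        assert common_associates(state, ("a", "b")) == 0

    def test_triangle(self):
        state = apply_all([("a", "b"), ("a", "c"), ("b", "c")])
        assert common_associates(state, ("a", "b"), same_class_only=True) == 1

    def test_same_class_only_undefined_for_mixed_dyad(self):
        state = apply_all([("a", "d")])
        with pytest.raises(ValueError):
            common_associates(state, ("a", "d"), same_class_only=True)

    def test_matches_bruteforce_set_intersection(self, rng):
        rows = random_history(rng, n=120)
        state = apply_all(rows)
        ids = list(CLASSES)
        for a in ids:
            for b in ids:
                if a >= b:
                    continue
                pa = {t if s == a else s for s, t in rows if a in (s, t)}
                pb = {t if s == b else s for s, t in rows if b in (s, t)}
                shared = (pa & pb) - {a, b}
                assert common_associates(state, (a, b)) == len(shared)
                if CLASSES[a] == CLASSES[b]:
                    same = {x for x in shared if CLASSES[x] == CLASSES[a]}
                    got = common_associates(state, (a, b), same_class_only=True)
                    assert got == len(same)
                    assert got <= common_associates(state, (a, b))


class TestBuildDesign:
    def events_and_nonevents(self, rng, n=50):
        obs = make_events(
            [
                dict(
                    source=s,
                    target=t,
                    day=i // 10,
                    is_same_class=CLASSES[s] == CLASSES[t],
                    is_affiliate=bool(i % 3 == 0),
                )
                for i, (s, t) in enumerate(random_history(rng, n))
            ]
        )
        ids = list(CLASSES)
        rows = []
        for _ in range(n):
            s, t = rng.choice(ids, size=2, replace=False)
            rows.append((s, t))
        non = obs.copy()
        non["source"] = [r[0] for r in rows]
        non["target"] = [r[1] for r in rows]
        return obs, non

    def test_first_event_has_zero_history(self, rng):
        obs, non = self.events_and_nonevents(rng, n=5)
        design = build_design(obs, non, "M8", CLASSES)
        first = design[design["event_index"] == 1]
        assert (first[list(MODEL_REGISTRY["M8"].terms)].to_numpy() == 0).all()

    def test_clock_scaling_per_thousand(self):
        obs = make_events(
            [
                dict(source="a", target="b", is_same_class=True, is_affiliate=False),
                dict(source="a", target="c", is_same_class=True, is_affiliate=False),
            ]
        )
        obs.loc[1, "index"] = 1000  # late-experiment event
        design = build_design(obs, obs, "M3", CLASSES)
        late = design[design["event_index"] == 1000].iloc[0]
        assert late["same_class_x_clock"] == pytest.approx(1.0)

    def test_unknown_model_rejected(self, rng):
        obs, non = self.events_and_nonevents(rng, n=3)
        with pytest.raises(ValueError):
            build_design(obs, non, "M99", CLASSES)

    def test_misaligned_inputs_rejected(self, rng):
        obs, non = self.events_and_nonevents(rng, n=4)
        with pytest.raises(ValueError):
            build_design(obs, non.head(3), "M3", CLASSES)

    @pytest.mark.parametrize("model_id", list(MODEL_REGISTRY))
    def test_incremental_equals_from_scratch(self, rng, model_id):
        """Covariates at index k match a fresh state built on events 1..k-1."""
        obs, non = self.events_and_nonevents(rng)
        design = build_design(obs, non, model_id, CLASSES)
        model = MODEL_REGISTRY[model_id]
        pairs = design[design["is_observed"]]
        for _, row in pairs.sample(n=min(12, len(pairs)), random_state=0).iterrows():
            k = int(row["event_index"])
            state = NetworkState(CLASSES)
            for r in obs.itertuples():
                if r.index < k:
                    state.apply(r.source, r.target)
            o = obs[obs["index"] == k].iloc[0]
            if model.needs_history:
                expected = model.per_event(
                    state,
                    EventView(
                        o["source"], o["target"], k, o["latency"], o["duration"]
                    ),
                )
            else:
                same = float(CLASSES[o["source"]] == CLASSES[o["target"]])
                if model_id == "M3":
                    expected = (same, same * k / 1000.0)
                elif model_id == "M6":
                    expected = (o["latency"] * same,)
                else:
                    expected = (o["duration"] * same,)
            got = tuple(row[t] for t in model.terms)
            assert got == pytest.approx(expected)

    def test_nonevents_never_update_state(self, rng):
        obs, non1 = self.events_and_nonevents(rng)
        _, non2 = self.events_and_nonevents(rng)
        d1 = build_design(obs, non1, "M1", CLASSES)
        d2 = build_design(obs, non2, "M1", CLASSES)
        cols = list(MODEL_REGISTRY["M1"].terms)
        pd.testing.assert_frame_equal(
            d1[d1["is_observed"]][cols].reset_index(drop=True),
            d2[d2["is_observed"]][cols].reset_index(drop=True),
        )

    def test_subset_restrictions(self, rng):
        obs, non = self.events_and_nonevents(rng)
        d4 = build_design(obs, non, "M4", CLASSES)
        d5 = build_design(obs, non, "M5", CLASSES)
        aff = obs["is_affiliate"].sum()
        assert len(d5) == 2 * aff
        assert len(d4) == 2 * (len(obs) - aff)
        d1 = build_design(obs, non, "M1", CLASSES)
        assert len(d1) == 2 * obs["is_same_class"].sum()

    def test_pairs_share_stratum_and_clock(self, rng):
        obs, non = self.events_and_nonevents(rng)
        d = build_design(obs, non, "M3", CLASSES)
        cases = d[d["is_observed"]].reset_index(drop=True)
        ctrls = d[~d["is_observed"]].reset_index(drop=True)
        assert (cases["event_index"].to_numpy() == ctrls["event_index"].to_numpy()).all()
        assert (cases["stratum"].to_numpy() == ctrls["stratum"].to_numpy()).all()
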