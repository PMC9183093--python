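"""Predicates and progressive-filtering behavior of the identification key."""
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from botakey.keyengine import (
    EmptyHistoryError,
    Observation,
    Tolerance,
    UnknownTraitError,
    apply_filter,
    identify,
    match_categorical,
    match_month,
    match_numeric,
    match_taxon,
    match_text,
    new_session,
    undo,
)
from botakey.synthgen import FloraSimConfig, draw_specimen, generate_flora
from botakey.traitbase import TaxonRow, TraitMatrix, apply_schema_config


class TestMatchNumeric:
    @pytest.mark.parametrize("observed,lower,upper,slack,expected", [
        (12, 10, 20, 0, True),       # interior point
        (10, 10, 20, 0, True),       # closed at the lower end
        (20, 10, 20, 0, True),       # closed at the upper end
        (9.99, 10, 20, 0, False),
        (21, 10, 20, 1, True),       # loose border: slack extends the interval
        (21.5, 10, 20, 1, False),
        (9, 10, 20, 1, True),
        (12, None, None, 0, True),   # no data: forgiving
        (5, None, 20, 0, True),      # one-sided bound
        (25, None, 20, 0, False),
    ])
    def test_closed_interval_with_slack(self, observed, lower, upper, slack, expected):
        assert match_numeric(observed, lower, upper, slack) is expected

    def test_negative_slack_rejected(self):
        with pytest.raises(ValueError):
            match_numeric(1, 0, 2, -0.5)


class TestMatchMonth:
    def test_exhaustive_against_circular_enumeration(self):
        """Every (month, since, until) triple agrees with explicit enumeration
        of the months the window contains."""
        for since in range(1, 13):
            for until in range(1, 13):
                if since <= until:
                    window = set(range(since, until + 1))
                else:
                    window = set(range(since, 13)) | set(range(1, until + 1))
                for observed in range(1, 13):
                    assert match_month(observed, since, until) == (observed in window)

    @pytest.mark.parametrize("observed,expected", [(1, True), (11, True),
                                                   (2, True), (7, False)])
    def test_wrapping_window_november_to_february(self, observed, expected):
        assert match_month(observed, 11, 2) is expected

    def test_missing_bound_matches_any_month(self):
        assert match_month(7, None, 2) and match_month(7, 11, None)

    def test_month_domain_enforced(self):
        with pytest.raises(ValueError):
            match_month(13, 1, 12)


class TestMatchCategoricalAndText:
    def test_membership_and_missing(self):
        assert match_categorical("yellow", frozenset({"yellow", "white"}))
        assert match_categorical("yellow", None)
        assert not match_categorical("pink", frozenset({"yellow"}))

    def test_normalization_of_both_sides(self):
        assert match_categorical("Yellow ", frozenset({"yellow"}))
        assert match_categorical("yellow", frozenset({" YELLOW"}))

    def test_text_substring_containment(self):
        assert match_text("cliff", "windswept cliffs")
        assert match_text("cliff", None)
        assert not match_text("clay", "calcareous")
        assert match_text("CLIFF", "Windswept Cliffs")


class TestMatchTaxon:
    def test_empty_conjunction_accepts_every_row(self, tiny_flora):
        for row in tiny_flora:
            assert match_taxon(tiny_flora, row, [])

    def test_row_missing_every_observed_trait_survives(self, tiny_flora):
        bare = TaxonRow("Ononis natrix", {})
        flora = TraitMatrix(tiny_flora.schema, [bare])
        obs = [Observation("corolla_color", "yellow"),
               Observation("plant_height", 55.0),
               Observation("flowering", 3)]
        assert match_taxon(flora, bare, obs)

    def test_unknown_trait_raises(self, tiny_flora):
        with pytest.raises(UnknownTraitError):
            match_taxon(tiny_flora, tiny_flora.rows[0],
                        [Observation("petal_count", 5)])

    def test_agrees_with_independent_predicate_oracle(self):
        """Random row x observation sets equal a brute-force evaluation that
        tests each predicate independently and ANDs the results."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            flora = generate_flora(FloraSimConfig(n_taxa=15, seed=trial,
                                                  missing_rate=0.3))
            schema = flora.schema
            pairs = schema.pairs()
            obs = []
            for gid, (lo, hi) in pairs.items():
                if lo.kind == "numeric_pair" and rng.random() < 0.5:
                    obs.append(Observation(gid, float(rng.uniform(0, 100))))
            obs.append(Observation("flowering", int(rng.integers(1, 13))))
            obs.append(Observation("corolla_color",
                                   ["yellow", "pink", "blue"][trial % 3]))
            for row in flora:
                verdicts = []
                for o in obs:  # oracle: per-predicate, AND afterwards
                    t = schema.resolve(o.trait_id)
                    if t.kind == "numeric_pair":
                        lo, hi = pairs[t.group]
                        verdicts.append(match_numeric(
                            o.value, row.get(lo.trait_id), row.get(hi.trait_id), 0))
                    elif t.kind == "month_window":
                        lo, hi = pairs[t.group]
                        verdicts.append(match_month(
                            o.value, row.get(lo.trait_id), row.get(hi.trait_id)))
                    else:
                        verdicts.append(match_categorical(o.value, row.get(t.trait_id)))
                assert match_taxon(flora, row, obs) == all(verdicts)


class TestSession:
    def test_skip_leaves_candidates_unchanged(self, tiny_flora):
        s0 = new_session(tiny_flora)
        s1 = apply_filter(s0, Observation.skipped("corolla_color"))
        assert s1.candidates.names == s0.candidates.names
        assert len(s1.observations) == 1
        assert len(s1.snapshots) == 1  # snapshots only for answered steps

    def test_answered_step_shrinks_or_keeps(self, tiny_flora):
        s = new_session(tiny_flora)
        s = apply_filter(s, Observation("corolla_color", "purple"))
        assert set(s.candidates.names) <= set(tiny_flora.taxon_names)
        assert s.counts == [3, 2]

    def test_undo_restores_previous_state(self, tiny_flora):
        s = new_session(tiny_flora)
        s1 = apply_filter(s, Observation("corolla_color", "purple"))
        s2 = apply_filter(s1, Observation("plant_height", 70.0))
        assert undo(s2).candidates.names == s1.candidates.names
        assert undo(undo(s2)).candidates.names == s.candidates.names

    def test_undo_on_fresh_session_errors(self, tiny_flora):
        with pytest.raises(EmptyHistoryError):
            undo(new_session(tiny_flora))

    def test_order_independence_of_terminal_set(self, tiny_flora):
        obs = [Observation("corolla_color", "purple"),
               Observation("plant_height", 35.0),
               Observation("flowering", 6),
               Observation.skipped("habitat")]
        rng = np.random.default_rng(3)
        reference = identify(tiny_flora, obs).candidates.names
        for _ in range(10):
            perm = [obs[i] for i in rng.permutation(len(obs))]
            assert identify(tiny_flora, perm).candidates.names == reference


class TestIdentify:
    def test_constructed_discriminant_determines(self, tiny_flora):
        session = identify(tiny_flora, [Observation("corolla_color", "yellow")])
        assert session.outcome == "determined"
        assert session.candidates.names == ("Lotus corniculatus",)

    def test_contradictory_observation_yields_no_match(self, tiny_flora):
        session = identify(tiny_flora, [Observation("plant_height", 4000.0)])
        assert session.outcome == "no_match" and len(session.candidates) == 0

    def test_ambiguous_outcome_reported_not_resolved(self, tiny_flora):
        session = identify(tiny_flora, [Observation("corolla_color", "purple")])
        assert session.outcome == "ambiguous"
        assert set(session.candidates) == {"Trifolium pratense", "Medicago sativa"}

    def test_log_records_trace_the_trimming(self, tiny_flora):
        session = identify(tiny_flora, [
            Observation("corolla_color", "purple"),
            Observation.skipped("habitat"),
            Observation("flowering", 1),
        ])
        recs = session.log_records()
        assert [r["remaining"] for r in recs] == [2, 2, 1]
        assert recs[1]["status"] == "skipped"
        assert recs[2]["remaining_names"] == ["Trifolium pratense"]

    def test_slack_monotonicity(self):
        """Increasing any slack never shrinks the terminal candidate set."""
        flora = generate_flora(FloraSimConfig(n_taxa=60, seed=11))
        obs = [Observation("plant_height", 42.0),
               Observation("corolla_length", 11.0),
               Observation("altitude", 700.0)]
        previous = None
        for slack in (0.0, 0.5, 2.0, 10.0, 1e6):
            tol = Tolerance({"plant_height": slack, "corolla_length": slack,
                             "altitude": slack})
            names = set(identify(flora, obs, tol).candidates)
            if previous is not None:
                assert previous <= names
            previous = names
        assert previous == set(flora.taxon_names)  # huge slack accepts all

    def test_unknown_vocabulary_token_warns_but_filters(self, schema, caplog):
        closed = apply_schema_config(
            schema, {"vocabulary": {"corolla_color": ["yellow", "white"]}})
        row = TaxonRow("Vicia faba", {"corolla_color": frozenset({"yellow"})})
        flora = TraitMatrix(closed, [row])
        with caplog.at_level(logging.WARNING):
            session = identify(flora, [Observation("corolla_color", "crimson")])
        assert session.outcome == "no_match"
        assert any("vocabulary" in r.message for r in caplog.records)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_specimen_from_own_ranges_is_always_retained(seed):
    """Answers drawn inside a taxon's stored ranges never eliminate it."""
    flora = generate_flora(FloraSimConfig(n_taxa=25, seed=seed % 97,
                                          missing_rate=0.2))
    if len(flora) == 0:
        return
    taxon = flora.taxon_names[seed % len(flora)]
    obs = draw_specimen(flora, taxon, noise=0.0, answer_rate=1.0, seed=seed)
    assert taxon in identify(flora, obs).candidates
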