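"""Diagnostic-rule unit and property tests."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itqcc.instrument import (
    DEFAULT_VARIANT_CHOICE,
    DUAL_VARIANT_ITEMS,
    ITEMS,
    SYMPTOM_CLUSTERS,
    CheckAnswer,
    Cluster,
    InconsistentRecordError,
    InvalidInputError,
    ItemId,
    Scale,
    ScoringMode,
    cluster_met,
    diagnose,
    gated_symptom_present,
    impairment_met,
    select_check_variant,
    symptom_present,
)

from conftest import make_record, migration_record

UNGATED = ScoringMode(gated=False)
GATED = ScoringMode(gated=True)


class TestItemTaxonomy:
    def test_eighteen_items_with_cluster_sizes(self):
        assert len(ITEMS) == 18
        by_cluster = {}
        for item in ITEMS:
            by_cluster.setdefault(item.cluster, []).append(item)
        for cluster, members in by_cluster.items():
            assert len(members) == (3 if cluster.is_impairment else 2)

    def test_scale_assignment(self):
        assert Cluster.RE.scale is Scale.PTSD
        assert Cluster.PTSD_FI.scale is Scale.PTSD
        assert Cluster.AD.scale is Scale.DSO
        assert Cluster.DSO_FI.scale is Scale.DSO

    def test_out_of_range_index_rejected(self):
        with pytest.raises(InvalidInputError):
            ItemId(Cluster.RE, 3)
        with pytest.raises(InvalidInputError):
            ItemId(Cluster.PTSD_FI, 4)


class TestEndorsementRule:
    @pytest.mark.parametrize("score,expected", [(0, False), (1, False), (2, True), (3, True), (4, True)])
    def test_moderately_or_higher(self, score, expected):
        assert symptom_present(score) is expected

    @pytest.mark.parametrize("bad", [-1, 5, 2.5, "2", None, True])
    def test_invalid_scores_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            symptom_present(bad)

    def test_gated_requires_yes(self):
        item = ItemId(Cluster.RE, 1)
        rec_yes = make_record({"ptsd_re1": 3}, {"ptsd_re1": "yes"})
        rec_no = make_record({"ptsd_re1": 3}, {"ptsd_re1": "no"})
        assert gated_symptom_present(rec_yes, item, GATED)
        assert not gated_symptom_present(rec_no, item, GATED)
        # ungated mode ignores the check entirely
        assert gated_symptom_present(rec_no, item, UNGATED)

    def test_gating_never_adds_endorsements(self):
        rec = make_record({"ptsd_re1": 1})
        assert not gated_symptom_present(rec, ItemId(Cluster.RE, 1), GATED)

    def test_endorsed_item_without_check_is_inconsistent(self):
        rec = make_record({"ptsd_re1": 3}, autofill_checks=None)
        assert rec.validate_gating()  # the invariant is violated ...
        with pytest.raises(InconsistentRecordError):
            gated_symptom_present(rec, ItemId(Cluster.RE, 1), GATED)

    def test_variant_choice_selects_which_check_counts(self):
        item = ItemId(Cluster.DR, 1)  # feeling cut off: default variant 2
        rec = make_record({"dso_dr1": 3}, {"dso_dr1": "yes", ("dso_dr1", 2): "no"})
        assert not gated_symptom_present(rec, item, GATED)  # variant 2 says no
        mode_v1 = ScoringMode(gated=True, variant_choice={item: 1})
        assert gated_symptom_present(rec, item, mode_v1)


class TestClusterAndImpairment:
    def test_cluster_met_matches_brute_force_over_all_configurations(self):
        """Exhaustive oracle: all 5x5 score pairs x 4 check-answer pairs."""
        cluster = Cluster.TH
        cols = ["ptsd_th1", "ptsd_th2"]
        for s1, s2 in itertools.product(range(5), repeat=2):
            for a1, a2 in itertools.product(["yes", "no"], repeat=2):
                rec = make_record({cols[0]: s1, cols[1]: s2}, {cols[0]: a1, cols[1]: a2})
                # independent statement of the rule: at least one item with
                # score >= 2 whose check (if consulted) was answered yes
                expect_ungated = (s1 >= 2) or (s2 >= 2)
                expect_gated = (s1 >= 2 and a1 == "yes") or (s2 >= 2 and a2 == "yes")
                assert cluster_met(rec, cluster, UNGATED) == expect_ungated
                assert cluster_met(rec, cluster, GATED) == expect_gated

    def test_impairment_any_of_three_with_gating(self):
        """Enumerate the 5^3 x {yes,no}^3 impairment configurations."""
        cols = ["dso_fi1", "dso_fi2", "dso_fi3"]
        for scores in itertools.product([0, 1, 2, 4], repeat=3):
            for answers in itertools.product(["yes", "no"], repeat=3):
                rec = make_record(dict(zip(cols, scores)), dict(zip(cols, answers)))
                expect_u = any(s >= 2 for s in scores)
                expect_g = any(s >= 2 and a == "yes" for s, a in zip(scores, answers))
                assert impairment_met(rec, Scale.DSO, UNGATED) == expect_u
                assert impairment_met(rec, Scale.DSO, GATED) == expect_g

    def test_impairment_high_score_failed_check(self):
        rec = make_record({"ptsd_fi1": 4, "ptsd_fi2": 1, "ptsd_fi3": 0}, {"ptsd_fi1": "no"})
        assert impairment_met(rec, Scale.PTSD, UNGATED)
        assert not impairment_met(rec, Scale.PTSD, GATED)

    def test_unknown_cluster_rejected(self):
        rec = make_record()
        with pytest.raises(InvalidInputError):
            cluster_met(rec, Cluster.PTSD_FI, UNGATED)
        with pytest.raises(InvalidInputError):
            cluster_met(rec, "re", UNGATED)


class TestDiagnosis:
    def test_maximal_record_is_cptsd(self):
        rec = make_record({item.column: 4 for item in ITEMS})
        assert diagnose(rec, UNGATED).label == "cptsd"
        assert diagnose(rec, GATED).label == "cptsd"  # all checks auto-yes

    def test_ptsd_without_full_dso(self):
        scores = {c: 3 for c in ["ptsd_re1", "ptsd_av1", "ptsd_th1", "ptsd_fi1",
                                 "dso_nsc1", "dso_dr1", "dso_fi1"]}  # AD cluster absent
        rec = make_record(scores)
        res = diagnose(rec, UNGATED)
        assert res.label == "ptsd"
        assert res.ptsd_part and not res.dso_part

    def test_dso_only_is_none(self):
        scores = {c: 3 for c in ["dso_ad1", "dso_nsc1", "dso_dr1", "dso_fi1"]}
        rec = make_record(scores)
        res = diagnose(rec, UNGATED)
        assert res.dso_part and res.label == "none"

    def test_cptsd_to_ptsd_migration_under_gating(self):
        rec = migration_record()
        assert diagnose(rec, UNGATED).label == "cptsd"
        assert diagnose(rec, GATED).label == "ptsd"

    def test_exposure_filter(self):
        rec = make_record({item.column: 4 for item in ITEMS})  # zero exposures
        mode = ScoringMode(gated=False, require_exposure=True)
        assert diagnose(rec, mode).label == "none"
        rec2 = make_record({item.column: 4 for item in ITEMS}, exposures=(1,) + (0,) * 20)
        assert diagnose(rec2, mode).label == "cptsd"

    def test_missing_scores_strict_vs_lenient(self):
        rec = make_record({"ptsd_re1": 3})
        rec.items[ItemId(Cluster.AV, 1)] = None
        with pytest.raises(InvalidInputError):
            diagnose(rec, UNGATED)
        res = diagnose(rec, ScoringMode(gated=False, lenient_missing=True))
        assert res.label == "none"


class TestVariantSelection:
    @pytest.mark.parametrize(
        "decreases,expected",
        [
            ({1: 94, 2: 76}, 1),   # numbing: trial check 1 retained
            ({1: 53, 2: 71}, 2),   # feeling cut off: trial check 2 retained
            ({1: 10, 2: 10}, 1),   # tie -> lowest variant id
        ],
    )
    def test_largest_decrease_retained(self, decreases, expected):
        assert select_check_variant(decreases) == expected

    def test_empty_and_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            select_check_variant({})
        with pytest.raises(InvalidInputError):
            select_check_variant({1: -2})

    def test_default_variant_choice_matches_selection_rule(self):
        numbing, cutoff = DUAL_VARIANT_ITEMS
        assert DEFAULT_VARIANT_CHOICE[numbing] == select_check_variant({1: 94, 2: 76})
        assert DEFAULT_VARIANT_CHOICE[cutoff] == select_check_variant({1: 53, 2: 71})


# --- property tests --------------------------------------------------------

record_strategy = st.builds(
    make_record,
    scores=st.fixed_dictionaries({item.column: st.integers(0, 4) for item in ITEMS}),
    checks=st.fixed_dictionaries(
        {
            **{item.column: st.sampled_from(["yes", "no"]) for item in ITEMS},
            **{(item.column, 2): st.sampled_from(["yes", "no"]) for item in DUAL_VARIANT_ITEMS},
        }
    ),
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(rec=record_strategy)
def test_gating_is_monotone_for_items_clusters_and_cptsd(rec):
    for item in ITEMS:
        if gated_symptom_present(rec, item, GATED):
            assert gated_symptom_present(rec, item, UNGATED)
    for cluster in SYMPTOM_CLUSTERS:
        if cluster_met(rec, cluster, GATED):
            assert cluster_met(rec, cluster, UNGATED)
    du, dg = diagnose(rec, UNGATED), diagnose(rec, GATED)
    if dg.label == "cptsd":
        assert du.label == "cptsd"
    if dg.any_disorder:
        assert du.any_disorder


@settings(max_examples=200, deadline=None, derandomize=True)
@given(rec=record_strategy)
def test_labels_mutually_exclusive_and_consistent(rec):
    for mode in (UNGATED, GATED):
        res = diagnose(rec, mode)
        assert res.label in ("none", "ptsd", "cptsd")
        if res.label == "cptsd":
            assert res.ptsd_part and res.dso_part
        elif res.label == "ptsd":
            assert res.ptsd_part and not res.dso_part
        else:
            assert not res.ptsd_part


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    scores=st.fixed_dictionaries({item.column: st.integers(0, 4) for item in ITEMS})
)
def test_all_yes_checks_reproduce_plain_itq(scores):
    """Identity limit: gating with every check answered yes changes nothing."""
    rec = make_record(scores, autofill_checks="yes")
    assert diagnose(rec, GATED) == diagnose(rec, UNGATED)
    for item in ITEMS:
        assert gated_symptom_present(rec, item, GATED) == gated_symptom_present(rec, item, UNGATED)
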