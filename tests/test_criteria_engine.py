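"""The calculator itself: risk groups, manifestation resolution, diagnosis."""

import itertools

import pytest

from arfdx import (
    ADVISORY_DIFFERENTIAL,
    ADVISORY_ECHO_PENDING,
    ADVISORY_HISTORY_UNVERIFIED,
    ADVISORY_SPECIALIST,
    CarditisStatus,
    Category,
    JointFinding,
    Judgement,
    ManifestationProfile,
    PatientPresentation,
    PriorHistory,
    RiskBasis,
    RiskGroup,
    RiskIndeterminateError,
    RiskLevel,
    StrepEvidence,
    assess_strep_evidence,
    assign_diagnosis,
    assign_risk_group,
    classify_manifestations,
    default_thresholds,
    diagnose,
)
from oracles import oracle_category

THRESHOLDS = default_thresholds()

NO_STREP = StrepEvidence(status="no-evidence-or-unmeasured")
STREP = StrepEvidence(status="evidence", basis=("rising-titres",))

_MAJOR_POOL = ("carditis", "sydenham-chorea", "erythema-marginatum")
_MINOR_POOL = (
    "fever",
    "elevated-inflammatory-markers",
    "prolonged-pr-interval",
    "monoarthralgia",
)


def profile(n_major: int, n_minor: int) -> ManifestationProfile:
    return ManifestationProfile(
        majors=frozenset(_MAJOR_POOL[:n_major]),
        minors=frozenset(_MINOR_POOL[:n_minor]),
    )


def pres(**kw) -> PatientPresentation:
    base = dict(
        age=10.0,
        indigenous_rural_remote=True,
        prior_arf_rhd=PriorHistory.CONFIRMED_NONE,
    )
    base.update(kw)
    return PatientPresentation(**base)


class TestRiskGroup:
    @pytest.mark.parametrize(
        "fields, level, basis",
        [
            # precedence: override > Indigenous rural/remote > epidemiology
            (
                {"risk_group_override": "low", "indigenous_rural_remote": True},
                RiskLevel.LOW,
                RiskBasis.EXPLICIT_OVERRIDE,
            ),
            (
                {"risk_group_override": "high", "community_incidence": 1.0},
                RiskLevel.HIGH,
                RiskBasis.EXPLICIT_OVERRIDE,
            ),
            (
                {"indigenous_rural_remote": True, "community_incidence": 1.0},
                RiskLevel.HIGH,
                RiskBasis.INDIGENOUS_RURAL_REMOTE,
            ),
            ({"community_incidence": 31.0}, RiskLevel.HIGH, RiskBasis.EPIDEMIOLOGY),
            # strict cutoff: exactly 30/100,000 is NOT high risk
            ({"community_incidence": 30.0}, RiskLevel.LOW, RiskBasis.EPIDEMIOLOGY),
            ({"community_rhd_prevalence": 2.1}, RiskLevel.HIGH, RiskBasis.EPIDEMIOLOGY),
            ({"community_rhd_prevalence": 2.0}, RiskLevel.LOW, RiskBasis.EPIDEMIOLOGY),
            (
                {"indigenous_rural_remote": False},
                RiskLevel.LOW,
                RiskBasis.INDIGENOUS_RURAL_REMOTE,
            ),
            (
                {"community_incidence": 5.0, "community_rhd_prevalence": 3.0},
                RiskLevel.HIGH,
                RiskBasis.EPIDEMIOLOGY,
            ),
        ],
    )
    def test_precedence_table(self, fields, level, basis):
        p = PatientPresentation(age=10, **fields)
        g = assign_risk_group(p, THRESHOLDS)
        assert g.value is level
        assert g.basis is basis

    def test_no_risk_input_is_indeterminate(self):
        with pytest.raises(RiskIndeterminateError):
            assign_risk_group(PatientPresentation(age=10), THRESHOLDS)


HIGH = RiskGroup(value=RiskLevel.HIGH, basis=RiskBasis.EXPLICIT_OVERRIDE)
LOW = RiskGroup(value=RiskLevel.LOW, basis=RiskBasis.EXPLICIT_OVERRIDE)


class TestManifestationClassification:
    def test_high_risk_monoarthritis_fever_crp(self, flat_uln):
        """Culture-negative monoarthritis in a high-risk child with fever
        and raised CRP resolves to one major and two minors."""
        p = pres(
            joint_finding=JointFinding.ASEPTIC_MONOARTHRITIS,
            max_temperature=38.6,
            crp=40.0,
        )
        m = classify_manifestations(p, HIGH, THRESHOLDS, flat_uln)
        assert m.majors == {"aseptic-monoarthritis"}
        assert m.minors == {"fever", "elevated-inflammatory-markers"}

    def test_low_risk_monoarthralgia_counts_for_nothing(self, flat_uln):
        p = pres(joint_finding=JointFinding.MONOARTHRALGIA)
        m = classify_manifestations(p, LOW, THRESHOLDS, flat_uln)
        assert m.majors == frozenset() and m.minors == frozenset()

    @pytest.mark.parametrize(
        "joint, group, expect",
        [
            (JointFinding.POLYARTHRITIS, HIGH, "major"),
            (JointFinding.ASEPTIC_MONOARTHRITIS, HIGH, "major"),
            (JointFinding.POLYARTHRALGIA, HIGH, "major"),
            (JointFinding.MONOARTHRALGIA, HIGH, "minor"),
            (JointFinding.POLYARTHRITIS, LOW, "major"),
            (JointFinding.ASEPTIC_MONOARTHRITIS, LOW, "minor"),
            (JointFinding.POLYARTHRALGIA, LOW, "minor"),
            (JointFinding.MONOARTHRALGIA, LOW, None),
            (JointFinding.NONE, HIGH, None),
            (JointFinding.NONE, LOW, None),
        ],
    )
    def test_joint_placement_per_risk_group(self, flat_uln, joint, group, expect):
        m = classify_manifestations(
            pres(joint_finding=joint), group, THRESHOLDS, flat_uln
        )
        placed = (
            "major"
            if joint.value in m.majors
            else "minor" if joint.value in m.minors else None
        )
        assert placed == expect
        assert len((m.majors | m.minors)) <= 1

    @pytest.mark.parametrize(
        "group, temp, is_minor",
        [
            (HIGH, 38.0, True),   # inclusive threshold
            (HIGH, 37.9, False),
            (LOW, 38.0, False),   # low-risk threshold is 38.5
            (LOW, 38.5, True),
            (LOW, 38.4, False),
        ],
    )
    def test_fever_thresholds_by_group(self, flat_uln, group, temp, is_minor):
        m = classify_manifestations(
            pres(max_temperature=temp), group, THRESHOLDS, flat_uln
        )
        assert ("fever" in m.minors) == is_minor

    @pytest.mark.parametrize(
        "group, fields, is_minor",
        [
            (HIGH, {"esr": 30.0}, True),
            (HIGH, {"esr": 29.9}, False),
            (LOW, {"esr": 30.0}, False),  # low-risk ESR threshold is 60
            (LOW, {"esr": 60.0}, True),
            (HIGH, {"crp": 30.0}, True),  # CRP threshold shared by groups
            (LOW, {"crp": 30.0}, True),
            (LOW, {"crp": 29.0}, False),
            (HIGH, {"esr": 10.0, "crp": 35.0}, True),
            (HIGH, {}, False),
        ],
    )
    def test_inflammatory_marker_minor(self, flat_uln, group, fields, is_minor):
        m = classify_manifestations(pres(**fields), group, THRESHOLDS, flat_uln)
        assert ("elevated-inflammatory-markers" in m.minors) == is_minor

    @pytest.mark.parametrize(
        "carditis, pr, expect_major, expect_pr_minor",
        [
            # truth table: carditis state x PR relative to the 160 ms ULN
            (CarditisStatus.ABSENT, None, False, False),
            (CarditisStatus.ABSENT, 150.0, False, False),
            (CarditisStatus.ABSENT, 160.0, False, False),  # equal is normal
            (CarditisStatus.ABSENT, 180.0, False, True),
            (CarditisStatus.PRESENT, None, True, False),
            (CarditisStatus.PRESENT, 150.0, True, False),
            (CarditisStatus.PRESENT, 180.0, True, False),  # PR suppressed
            (CarditisStatus.ECHO_PENDING, None, False, False),
            (CarditisStatus.ECHO_PENDING, 180.0, False, True),
        ],
    )
    def test_carditis_pr_exclusion_truth_table(
        self, flat_uln, carditis, pr, expect_major, expect_pr_minor
    ):
        m = classify_manifestations(
            pres(carditis=carditis, pr_interval=pr), HIGH, THRESHOLDS, flat_uln
        )
        assert ("carditis" in m.majors) == expect_major
        assert ("prolonged-pr-interval" in m.minors) == expect_pr_minor

    def test_suppressed_pr_is_noted_for_audit(self, flat_uln):
        m = classify_manifestations(
            pres(carditis=CarditisStatus.PRESENT, pr_interval=200.0),
            HIGH,
            THRESHOLDS,
            flat_uln,
        )
        assert any("suppressed" in note for note in m.notes)

    def test_other_majors_count_in_both_groups(self, flat_uln):
        p = pres(chorea=True, erythema_marginatum=True, subcutaneous_nodules=True)
        for group in (HIGH, LOW):
            m = classify_manifestations(p, group, THRESHOLDS, flat_uln)
            assert m.majors == {
                "sydenham-chorea",
                "erythema-marginatum",
                "subcutaneous-nodules",
            }


class TestStrepEvidence:
    def test_elevated_adb_titre(self, flat_uln):
        s = assess_strep_evidence(pres(adb_titre=400.0), flat_uln)
        assert s.has_evidence and s.basis == ("elevated-adb-titre",)

    def test_no_serology_means_no_evidence(self, flat_uln):
        s = assess_strep_evidence(pres(), flat_uln)
        assert not s.has_evidence and s.basis == ()

    @pytest.mark.parametrize(
        "fields, evidence",
        [
            ({"aso_titre": 200.0}, False),  # exactly the ULN: within normal
            ({"aso_titre": 200.1}, True),
            ({"adb_titre": 300.0}, False),
            ({"adb_titre": 300.1}, True),
            ({"rising_titres": True}, True),
            ({"positive_throat_culture_or_rapid_test": True}, True),
            ({"aso_titre": 100.0, "adb_titre": 100.0}, False),
        ],
    )
    def test_uln_boundary_is_strict(self, flat_uln, fields, evidence):
        assert assess_strep_evidence(pres(**fields), flat_uln).has_evidence == evidence

    def test_basis_lists_every_contributing_finding(self, flat_uln):
        s = assess_strep_evidence(
            pres(aso_titre=500.0, adb_titre=500.0, rising_titres=True,
                 positive_throat_culture_or_rapid_test=True),
            flat_uln,
        )
        assert set(s.basis) == {
            "elevated-aso-titre",
            "elevated-adb-titre",
            "rising-titres",
            "positive-culture-or-rapid-test",
        }


class TestAssignDiagnosis:
    def test_one_major_two_minor_with_strep_is_definite(self):
        r = assign_diagnosis(profile(1, 2), STREP, PriorHistory.CONFIRMED_NONE)
        assert r.category is Category.DEFINITE
        assert r.pathway == (1, 2)
        assert not r.asked_clinician_question

    @pytest.mark.parametrize(
        "judgement, expected",
        [
            (Judgement.YES, Category.PROBABLE),
            (Judgement.UNCERTAIN, Category.POSSIBLE),
            (None, Category.POSSIBLE),
            (Judgement.NO, Category.NOT_ARF),
        ],
    )
    def test_shortfall_resolved_by_clinician_judgement(self, judgement, expected):
        r = assign_diagnosis(
            profile(1, 1), STREP, PriorHistory.CONFIRMED_NONE, judgement
        )
        assert r.category is expected
        assert r.asked_clinician_question

    def test_empty_presentation_not_arf_without_question(self):
        r = assign_diagnosis(profile(0, 0), NO_STREP, PriorHistory.CONFIRMED_NONE)
        assert r.category is Category.NOT_ARF
        assert not r.asked_clinician_question

    def test_recurrent_three_minor_pathway(self):
        definite = assign_diagnosis(
            profile(0, 3), STREP, PriorHistory.DOCUMENTED_HISTORY
        )
        assert definite.category is Category.DEFINITE
        assert definite.episode_type == "recurrent"
        assert definite.pathway == (0, 3)
        short = assign_diagnosis(
            profile(0, 2), STREP, PriorHistory.DOCUMENTED_HISTORY,
            Judgement.UNCERTAIN,
        )
        assert short.category is Category.POSSIBLE

    def test_three_minors_without_history_is_not_definite(self):
        r = assign_diagnosis(profile(0, 3), STREP, PriorHistory.CONFIRMED_NONE)
        assert r.category is not Category.DEFINITE

    def test_full_profile_without_strep_is_shortfall(self):
        r = assign_diagnosis(
            profile(2, 0), NO_STREP, PriorHistory.CONFIRMED_NONE, Judgement.YES
        )
        assert r.category is Category.PROBABLE

    def test_two_deficits_not_arf_without_question(self):
        # one minor short AND no strep evidence
        r = assign_diagnosis(profile(1, 1), NO_STREP, PriorHistory.CONFIRMED_NONE)
        assert r.category is Category.NOT_ARF
        assert not r.asked_clinician_question

    def test_unknown_history_assessed_as_initial_with_advisory(self):
        r = assign_diagnosis(profile(0, 3), STREP, PriorHistory.UNKNOWN)
        assert r.episode_type == "initial"
        assert r.category is not Category.DEFINITE
        assert ADVISORY_HISTORY_UNVERIFIED in r.advisories

    def test_fixed_advisories_on_every_result(self):
        for nmaj, nmin in [(0, 0), (1, 1), (2, 2)]:
            r = assign_diagnosis(
                profile(nmaj, nmin), STREP, PriorHistory.CONFIRMED_NONE
            )
            assert ADVISORY_DIFFERENTIAL in r.advisories
            assert ADVISORY_SPECIALIST in r.advisories

    def test_oracle_equivalence_over_full_cross_product(self):
        """Exhaustive agreement with an independent transcription of the
        criteria text over (n_major, n_minor, strep, episode, judgement)."""
        judgements = [None, Judgement.YES, Judgement.UNCERTAIN, Judgement.NO]
        for nmaj, nmin, strep, recurrent, judgement in itertools.product(
            range(4), range(5), (False, True), (False, True), judgements
        ):
            prior = (
                PriorHistory.DOCUMENTED_HISTORY
                if recurrent
                else PriorHistory.CONFIRMED_NONE
            )
            got = assign_diagnosis(
                profile(min(nmaj, 3), min(nmin, 4)),
                STREP if strep else NO_STREP,
                prior,
                judgement,
            )
            expected = oracle_category(
                nmaj, nmin, strep, recurrent,
                None if judgement is None else judgement.value,
            )
            assert got.category.label == expected, (
                nmaj, nmin, strep, recurrent, judgement,
            )

    def test_definite_always_has_strep_evidence(self):
        for nmaj, nmin, strep in itertools.product(
            range(4), range(5), (False, True)
        ):
            r = assign_diagnosis(
                profile(nmaj, nmin),
                STREP if strep else NO_STREP,
                PriorHistory.CONFIRMED_NONE,
            )
            if r.category is Category.DEFINITE:
                assert r.strep == "evidence"


class TestDiagnoseComposition:
    def test_high_risk_monoarthritis_case_is_definite(self, test_config):
        """Culture-negative monoarthritis + fever + raised CRP + elevated
        anti-DNase B in a high-risk patient, no carditis."""
        p = pres(
            joint_finding=JointFinding.ASEPTIC_MONOARTHRITIS,
            max_temperature=38.6,
            crp=40.0,
            adb_titre=500.0,
        )
        assert diagnose(p, test_config).category is Category.DEFINITE

    def test_joint_downgrade_drops_below_definite(self, test_config):
        """The same case read as monoarthralgia (pain, not arthritis)."""
        p = pres(
            joint_finding=JointFinding.MONOARTHRALGIA,
            max_temperature=38.6,
            crp=40.0,
            adb_titre=500.0,
            clinician_judgement=Judgement.UNCERTAIN,
        )
        assert diagnose(p, test_config).category < Category.DEFINITE

    def test_empty_low_risk_presentation(self, test_config):
        p = PatientPresentation(age=8, risk_group_override=RiskLevel.LOW)
        assert diagnose(p, test_config).category is Category.NOT_ARF

    def test_judgement_defaults_to_uncertain(self, test_config):
        p = pres(
            joint_finding=JointFinding.ASEPTIC_MONOARTHRITIS,
            max_temperature=38.6,
            aso_titre=500.0,
        )
        assert diagnose(p, test_config).category is Category.POSSIBLE

    def test_echo_pending_adds_advisory_and_counts_nothing(self, test_config):
        pending = pres(carditis=CarditisStatus.ECHO_PENDING)
        absent = pres(carditis=CarditisStatus.ABSENT)
        r_pending = diagnose(pending, test_config)
        r_absent = diagnose(absent, test_config)
        assert r_pending.category == r_absent.category
        assert ADVISORY_ECHO_PENDING in r_pending.advisories
        assert ADVISORY_ECHO_PENDING not in r_absent.advisories

    def test_determinism(self, test_config):
        p = pres(
            joint_finding=JointFinding.POLYARTHRITIS,
            max_temperature=39.0,
            esr=80.0,
            aso_titre=500.0,
        )
        assert diagnose(p, test_config) == diagnose(p, test_config)

    def test_risk_indeterminate_propagates(self, test_config):
        with pytest.raises(RiskIndeterminateError):
            diagnose(PatientPresentation(age=10), test_config)

    @pytest.mark.parametrize(
        "field, inert_value",
        [
            ("max_temperature", 37.0),   # below every fever threshold
            ("esr", 5.0),
            ("crp", 5.0),
            ("pr_interval", 100.0),      # below the injected 160 ms ULN
            ("aso_titre", 50.0),
            ("adb_titre", 50.0),
            ("chorea", False),
            ("rising_titres", False),
            ("positive_throat_culture_or_rapid_test", False),
        ],
    )
    def test_missing_data_inertness(self, test_config, field, inert_value):
        """A normal-range or explicitly negative optional field gives the
        same diagnosis as leaving the field out entirely."""
        base = dict(
            age=10.0,
            indigenous_rural_remote=True,
            prior_arf_rhd="confirmed-none",
            joint_finding="aseptic-monoarthritis",
            crp=40.0,
            adb_titre=500.0,
        )
        with_field = PatientPresentation(**{**base, field: inert_value})
        without = PatientPresentation(**{k: v for k, v in base.items() if k != field})
        assert diagnose(with_field, test_config) == diagnose(without, test_config)
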