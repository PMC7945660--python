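"""Rule engine: QC filter, panel restriction, pathogenicity classification."""
import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ird_triage.io_model import (
    AcmgClass,
    Consequence,
    PREDICTOR_TOOLS,
    Verdict,
    Zygosity,
)
from ird_triage.variant_triage import (
    PathogenicityCall,
    QcThresholds,
    apply_qc_filter,
    classify_pathogenicity,
    flag_for_validation,
    is_truncating,
    predictor_consensus,
    restrict_to_panel,
)
from ird_triage.io_model import PanelGene, Mode

from conftest import make_annotation, make_call


class TestQcFilter:
    def test_low_depth_removed(self):
        call = make_call(total_depth=9, alt_depth=4)
        assert apply_qc_filter([call]) == []

    def test_boundaries_kept(self):
        """Removal conditions are strict <, so exact thresholds survive."""
        call = make_call(total_depth=10, alt_depth=2, vaf=0.10)
        assert apply_qc_filter([call]) == [call]

    def test_low_vaf_removed(self):
        call = make_call(total_depth=100, alt_depth=9)  # vaf 0.09
        assert apply_qc_filter([call]) == []

    def test_low_alt_reads_removed(self):
        call = make_call(total_depth=10, alt_depth=1, vaf=0.5)
        assert apply_qc_filter([call]) == []

    def test_matches_bruteforce_oracle_on_random_calls(self):
        rng = np.random.default_rng(7)
        calls = []
        for i in range(10_000):
            depth = int(rng.integers(1, 40))
            alt = int(rng.integers(0, depth + 1))
            calls.append(
                make_call(pos=i + 1, total_depth=depth, alt_depth=alt)
            )
        thresholds = QcThresholds()
        expected = [
            c
            for c in calls
            if c.total_depth >= 10 and c.vaf >= 0.10 and c.alt_depth >= 2
        ]
        assert apply_qc_filter(calls, thresholds) == expected

    def test_idempotent_subset(self):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(200):
            depth = int(rng.integers(1, 30))
            calls.append(
                make_call(pos=i + 1, total_depth=depth,
                          alt_depth=int(rng.integers(0, depth + 1)))
            )
        once = apply_qc_filter(calls)
        assert set(c.key for c in once) <= set(c.key for c in calls)
        assert apply_qc_filter(once) == once

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            QcThresholds(min_depth=0)


class TestPanelRestriction:
    panel = [PanelGene("USH2A", frozenset({Mode.AR}), frozenset({"RP"}))]

    def test_on_panel_retained_off_panel_dropped(self):
        call_on = make_call(pos=100)
        call_off = make_call(pos=200)
        anns = {
            call_on.key: make_annotation(pos=100, gene="USH2A"),
            call_off.key: make_annotation(pos=200, gene="TTN"),
        }
        result = restrict_to_panel([call_on, call_off], anns, self.panel)
        assert [c.key for c, _ in result] == [call_on.key]

    def test_case_insensitive_symbol_match(self):
        call = make_call(pos=100)
        anns = {call.key: make_annotation(pos=100, gene="Ush2a")}
        assert len(restrict_to_panel([call], anns, self.panel)) == 1

    def test_unannotated_calls_dropped(self):
        call = make_call(pos=999)
        assert restrict_to_panel([call], {}, self.panel) == []

    def test_commutes_with_qc_filter(self):
        """QC filtering and panel restriction are order-independent."""
        rng = np.random.default_rng(11)
        calls, anns = [], {}
        for i in range(300):
            depth = int(rng.integers(1, 40))
            call = make_call(pos=i + 1, total_depth=depth,
                             alt_depth=int(rng.integers(0, depth + 1)))
            calls.append(call)
            gene = "USH2A" if rng.random() < 0.5 else "TTN"
            anns[call.key] = make_annotation(pos=i + 1, gene=gene)
        a = restrict_to_panel(apply_qc_filter(calls), anns, self.panel)
        b = [(c, ann) for c, ann in restrict_to_panel(calls, anns, self.panel)
             if apply_qc_filter([c])]
        assert a == b


class TestPredictorConsensus:
    def _verdicts(self, damaging, tolerated, missing):
        values = (
            [Verdict.DAMAGING] * damaging
            + [Verdict.TOLERATED] * tolerated
            + [Verdict.MISSING] * missing
        )
        return dict(zip(PREDICTOR_TOOLS, values))

    def test_four_of_six_is_consensus(self):
        assert predictor_consensus(self._verdicts(4, 2, 0)) is True

    def test_exactly_half_is_not(self):
        assert predictor_consensus(self._verdicts(3, 3, 0)) is False

    def test_missing_counts_against_under_fixed_denominator(self):
        assert predictor_consensus(self._verdicts(3, 0, 3)) is False
        # the same votes pass with the available-tools denominator
        assert predictor_consensus(self._verdicts(3, 0, 3), "available") is True

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            predictor_consensus({"sift": Verdict.DAMAGING})

    def test_full_enumeration_matches_strict_majority_predicate(self):
        """All 3^6 verdict vectors agree with the independent predicate."""
        for combo in itertools.product(list(Verdict), repeat=6):
            verdicts = dict(zip(PREDICTOR_TOOLS, combo))
            expected = sum(v is Verdict.DAMAGING for v in combo) > 3
            assert predictor_consensus(verdicts) == expected

    @given(st.permutations(list(range(6))))
    def test_permutation_invariant(self, perm):
        base = [Verdict.DAMAGING] * 4 + [Verdict.TOLERATED, Verdict.MISSING]
        verdicts = dict(zip(PREDICTOR_TOOLS, [base[i] for i in perm]))
        assert predictor_consensus(verdicts) is True


class TestTruncating:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            (Consequence.NONSENSE, True),
            (Consequence.FRAMESHIFT_INSERTION, True),
            (Consequence.FRAMESHIFT_DELETION, True),
            (Consequence.MISSENSE, False),
            (Consequence.SPLICING, False),  # qualifies only via criteria 1-3
            (Consequence.SYNONYMOUS, False),
            (Consequence.OTHER, False),
        ],
    )
    def test_closed_enum(self, consequence, expected):
        assert is_truncating(consequence) is expected


class TestClassifyPathogenicity:
    def test_known_alone_is_pathogenic(self):
        ann = make_annotation(known=True)
        call = classify_pathogenicity(ann)
        assert call.pathogenic and call.rationale == frozenset({"KNOWN"})

    def test_weak_evidence_is_not(self):
        ann = make_annotation(acmg=AcmgClass.UNCERTAIN, n_damaging=2)
        assert classify_pathogenicity(ann).pathogenic is False

    def test_all_criteria_recorded(self):
        ann = make_annotation(
            known=True, acmg=AcmgClass.PATHOGENIC,
            consequence=Consequence.NONSENSE, n_damaging=6,
        )
        assert classify_pathogenicity(ann).rationale == frozenset(
            {"KNOWN", "ACMG", "CONSENSUS", "TRUNCATING"}
        )

    def test_exhaustive_grid_matches_or_oracle(self):
        """known x acmg x damaging-count x consequence grid equals an
        independently coded OR of the four criteria (490+ combinations)."""
        for known in (False, True):
            for acmg in AcmgClass:
                for n_damaging in range(7):
                    for consequence in Consequence:
                        ann = make_annotation(
                            known=known, acmg=acmg, n_damaging=n_damaging,
                            consequence=consequence,
                        )
                        oracle = (
                            known
                            or acmg in (AcmgClass.PATHOGENIC, AcmgClass.LIKELY_PATHOGENIC)
                            or n_damaging >= 4
                            or consequence.value in (
                                "nonsense", "frameshift_insertion", "frameshift_deletion"
                            )
                        )
                        result = classify_pathogenicity(ann)
                        assert result.pathogenic == oracle
                        assert result.pathogenic == bool(result.rationale)

    @given(
        known=st.booleans(),
        acmg=st.sampled_from(list(AcmgClass)),
        n_damaging=st.integers(0, 5),
        consequence=st.sampled_from(list(Consequence)),
    )
    def test_monotone_in_each_input(self, known, acmg, n_damaging, consequence):
        """Strengthening any single pathogenicity signal never flips
        pathogenic -> non-pathogenic."""
        base = classify_pathogenicity(
            make_annotation(known=known, acmg=acmg, n_damaging=n_damaging,
                            consequence=consequence)
        ).pathogenic
        stronger = [
            make_annotation(known=True, acmg=acmg, n_damaging=n_damaging,
                            consequence=consequence),
            make_annotation(known=known, acmg=AcmgClass.PATHOGENIC,
                            n_damaging=n_damaging, consequence=consequence),
            make_annotation(known=known, acmg=acmg, n_damaging=n_damaging + 1,
                            consequence=consequence),
            make_annotation(known=known, acmg=acmg, n_damaging=n_damaging,
                            consequence=Consequence.NONSENSE),
        ]
        if base:
            for ann in stronger:
                assert classify_pathogenicity(ann).pathogenic

    def test_rationale_consistency_enforced(self):
        with pytest.raises(ValueError):
            PathogenicityCall(
                key=make_call().key, pathogenic=True, rationale=frozenset()
            )


class TestValidationFlagging:
    def test_strict_coverage_boundary(self):
        low = make_call(pos=1, total_depth=19, alt_depth=10)
        high = make_call(pos=2, total_depth=20, alt_depth=10)
        assert flag_for_validation([low, high]) == [low.key]

    def test_cohort_scale_fraction(self):
        """177 pathogenic calls of which 5 sit below 20x -> 5 flagged (2.8%)."""
        calls = [
            make_call(pos=i + 1, total_depth=15 if i < 5 else 50,
                      alt_depth=7 if i < 5 else 25)
            for i in range(177)
        ]
        flagged = flag_for_validation(calls)
        assert len(flagged) == 5
        assert round(100 * len(flagged) / len(calls), 1) == 2.8
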