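"""Mendelian diagnosis logic: compatibility filtering, status determination."""
import pytest

from ird_triage.diagnosis_engine import (
    Candidate,
    diagnose_patient,
    load_compatibility,
    phenotype_inheritance_filter,
    reclassify_cohort,
)
from ird_triage.io_model import (
    AcmgClass,
    Consequence,
    DiagnosisStatus,
    Mode,
    PanelGene,
    Patient,
    PedigreePattern,
    Sex,
    Zygosity,
)
from ird_triage.variant_triage import classify_pathogenicity

from conftest import make_annotation, make_call

PANEL = {
    g.symbol: g
    for g in [
        PanelGene("USH2A", frozenset({Mode.AR}), frozenset({"RP", "Usher"})),
        PanelGene("CHM", frozenset({Mode.XL}), frozenset({"choroideraemia"})),
        PanelGene("CYP4V2", frozenset({Mode.AR}), frozenset({"Bietti"})),
        PanelGene("RHO", frozenset({Mode.AD}), frozenset({"RP"})),
        PanelGene("RP1", frozenset({Mode.AD, Mode.AR}), frozenset({"RP", "MD"})),
        PanelGene("ABCA4", frozenset({Mode.AR}), frozenset({"STGD", "CORD", "RP"})),
    ]
}

COMPAT = load_compatibility()


def candidate(gene, pos, zygosity=Zygosity.HET, known=True, **ann_kwargs):
    call = make_call(pos=pos, zygosity=zygosity,
                     alt_depth=40 if zygosity is not Zygosity.HET else 20,
                     total_depth=40)
    ann = make_annotation(pos=pos, gene=gene, known=known, **ann_kwargs)
    patho = classify_pathogenicity(ann)
    assert patho.pathogenic
    return Candidate(call, ann, patho)


def patient(sex=Sex.MALE, clinical="RP", pedigree=PedigreePattern.SIMPLEX):
    return Patient("P1", sex, clinical, pedigree)


class TestPhenotypeInheritanceFilter:
    def test_rp_patient_keeps_mimicking_chm_gene(self):
        """Choroideraemia mimics RP clinically, so an RP presentation keeps
        XL CHM candidates (simplex pedigree excludes nothing on mode)."""
        cands = [candidate("CHM", 100, Zygosity.HEMI)]
        kept = phenotype_inheritance_filter(cands, patient(), PANEL, COMPAT)
        assert kept == cands

    def test_ad_pedigree_excludes_ar_only_gene(self):
        cands = [candidate("USH2A", 100)]
        kept = phenotype_inheritance_filter(
            cands, patient(pedigree=PedigreePattern.AD), PANEL, COMPAT
        )
        assert kept == []

    def test_ar_and_simplex_pedigrees_exclude_nothing_on_mode(self):
        cands = [candidate("RHO", 100)]
        for ped in (PedigreePattern.AR, PedigreePattern.SIMPLEX):
            assert phenotype_inheritance_filter(
                cands, patient(pedigree=ped), PANEL, COMPAT
            ) == cands

    def test_incompatible_phenotype_excluded(self):
        # A Stargardt presentation is not compatible with choroideraemia genes.
        cands = [candidate("CHM", 100, Zygosity.HEMI)]
        kept = phenotype_inheritance_filter(
            cands, patient(clinical="STGD"), PANEL, COMPAT
        )
        assert kept == []

    def test_or_mode_relaxes_conjunction(self):
        cands = [candidate("USH2A", 100)]
        p = patient(pedigree=PedigreePattern.AD)  # mode mismatch, phenotype ok
        assert phenotype_inheritance_filter(cands, p, PANEL, COMPAT, mode="or") == cands

    def test_empty_candidates(self):
        assert phenotype_inheritance_filter([], patient(), PANEL, COMPAT) == []


class TestDiagnosePatient:
    def test_hemizygous_chm_male_redefined_as_choroideraemia(self):
        cands = [candidate("CHM", 100, Zygosity.HEMI)]
        d = diagnose_patient(patient(), cands, PANEL, COMPAT)
        assert d.status is DiagnosisStatus.DEFINITE
        assert d.mode is Mode.XL and d.gene == "CHM"
        assert d.refined_diagnosis == "choroideraemia"

    def test_compound_het_cyp4v2_definite_ar_bietti(self):
        cands = [candidate("CYP4V2", 100), candidate("CYP4V2", 200)]
        d = diagnose_patient(patient(), cands, PANEL, COMPAT)
        assert d.status is DiagnosisStatus.DEFINITE
        assert d.mode is Mode.AR and len(d.causal_variants) == 2
        assert d.refined_diagnosis == "Bietti"

    def test_single_ar_het_is_possible(self):
        cands = [candidate("ABCA4", 100)]
        d = diagnose_patient(patient(clinical="STGD"), cands, PANEL, COMPAT)
        assert d.status is DiagnosisStatus.POSSIBLE
        assert d.gene == "ABCA4" and d.mode is Mode.AR

    def test_homozygous_ar_variant_is_definite(self):
        cands = [candidate("USH2A", 100, Zygosity.HOM)]
        d = diagnose_patient(patient(), cands, PANEL, COMPAT)
        assert d.status is DiagnosisStatus.DEFINITE
        assert sum(v.n_alleles for v in d.causal_variants) == 2

    def test_no_candidates_is_none(self):
        d = diagnose_patient(patient(), [], PANEL, COMPAT)
        assert d.status is DiagnosisStatus.NONE and d.gene is None
        assert d.refined_diagnosis == "RP"

    def test_two_hets_same_locus_are_one_allele(self):
        """Duplicate calls at one locus collapse; only 'possible' results."""
        cands = [candidate("USH2A", 100), candidate("USH2A", 100)]
        d = diagnose_patient(patient(), cands, PANEL, COMPAT)
        assert d.status is DiagnosisStatus.POSSIBLE

    def test_xl_het_female_is_carrier_by_default(self):
        cands = [candidate("CHM", 100, Zygosity.HET)]
        p = patient(sex=Sex.FEMALE)
        assert diagnose_patient(p, cands, PANEL, COMPAT).status is DiagnosisStatus.NONE
        d = diagnose_patient(p, cands, PANEL, COMPAT, xl_het_female="affected")
        assert d.status is DiagnosisStatus.DEFINITE

    def test_xl_hom_female_is_definite(self):
        cands = [candidate("CHM", 100, Zygosity.HOM)]
        d = diagnose_patient(patient(sex=Sex.FEMALE), cands, PANEL, COMPAT)
        assert d.status is DiagnosisStatus.DEFINITE and d.mode is Mode.XL

    def test_dual_mode_gene_compound_het_resolves_ar_not_ad(self):
        """A compound het in a dual-mode (AD+AR) gene under a non-AD pedigree
        is an AR diagnosis; a single het there is only 'possible'."""
        pair = [candidate("RP1", 100), candidate("RP1", 200)]
        d = diagnose_patient(patient(), pair, PANEL, COMPAT)
        assert d.mode is Mode.AR and d.status is DiagnosisStatus.DEFINITE
        single = [candidate("RP1", 100)]
        d2 = diagnose_patient(patient(), single, PANEL, COMPAT)
        assert d2.status is DiagnosisStatus.POSSIBLE

    def test_dual_mode_gene_ad_pedigree_single_het_definite(self):
        d = diagnose_patient(
            patient(pedigree=PedigreePattern.AD), [candidate("RP1", 100)],
            PANEL, COMPAT,
        )
        assert d.status is DiagnosisStatus.DEFINITE and d.mode is Mode.AD

    def test_definite_beats_possible_across_genes(self):
        cands = [
            candidate("ABCA4", 100),  # single AR het -> possible
            candidate("RHO", 300),  # AD het -> definite
        ]
        d = diagnose_patient(patient(), cands, PANEL, COMPAT)
        assert d.gene == "RHO" and d.status is DiagnosisStatus.DEFINITE

    def test_gene_tiebreak_by_rationale_strength_then_alpha(self):
        weak = [
            candidate("USH2A", 100, known=False, acmg=AcmgClass.LIKELY_PATHOGENIC),
            candidate("USH2A", 200, known=False, acmg=AcmgClass.LIKELY_PATHOGENIC),
        ]
        strong = [
            candidate("CYP4V2", 300, known=True),
            candidate("CYP4V2", 400, known=True),
        ]
        d = diagnose_patient(patient(), weak + strong, PANEL, COMPAT)
        assert d.gene == "CYP4V2"  # KNOWN (weight 3) beats ACMG (weight 2)

    def test_monotone_adding_allele_upgrades_status(self):
        """none -> possible -> definite as AR alleles accumulate."""
        p = patient()
        first = [candidate("USH2A", 100)]
        both = first + [candidate("USH2A", 200)]
        s0 = diagnose_patient(p, [], PANEL, COMPAT).status
        s1 = diagnose_patient(p, first, PANEL, COMPAT).status
        s2 = diagnose_patient(p, both, PANEL, COMPAT).status
        assert (s0, s1, s2) == (
            DiagnosisStatus.NONE, DiagnosisStatus.POSSIBLE, DiagnosisStatus.DEFINITE
        )

    def test_removing_second_ar_allele_downgrades_to_possible_same_gene(self):
        p = patient()
        both = [candidate("USH2A", 100), candidate("USH2A", 200)]
        d2 = diagnose_patient(p, both, PANEL, COMPAT)
        d1 = diagnose_patient(p, both[:1], PANEL, COMPAT)
        assert d2.status is DiagnosisStatus.DEFINITE
        assert d1.status is DiagnosisStatus.POSSIBLE and d1.gene == d2.gene

    def test_off_panel_gene_violates_contract(self):
        cands = [candidate("USH2A", 100)]
        with pytest.raises(KeyError):
            diagnose_patient(patient(), cands, {}, COMPAT)


class TestReclassification:
    def _dx(self, pid, mode, refined="RP"):
        c = candidate("USH2A", 100)
        from ird_triage.io_model import CausalVariant, MolecularDiagnosis

        causal = CausalVariant(
            chrom="chr1", pos=100, ref="A", alt="G",
            zygosity=Zygosity.HOM if mode is Mode.AR else Zygosity.HET,
            consequence=Consequence.MISSENSE, previously_reported=True,
            rationale=frozenset({"KNOWN"}),
        )
        return MolecularDiagnosis(
            patient_id=pid, status=DiagnosisStatus.DEFINITE, gene="USH2A",
            causal_variants=(causal,), mode=mode, refined_inheritance=mode,
            refined_diagnosis=refined,
        )

    def test_simplex_to_ar_counted_as_redefined(self):
        patients = [Patient("P1", Sex.MALE, "RP", PedigreePattern.SIMPLEX)]
        r = reclassify_cohort([self._dx("P1", Mode.AR)], patients)
        assert r.crosstab.loc["simplex", "AR"] == 1
        assert r.n_inheritance_redefined == 1
        assert r.simplex_by_mode == {"AD": 0, "AR": 1, "XL": 0}

    def test_concordant_pedigree_not_redefined(self):
        patients = [Patient("P1", Sex.MALE, "RP", PedigreePattern.AR)]
        r = reclassify_cohort([self._dx("P1", Mode.AR)], patients)
        assert r.n_inheritance_redefined == 0

    def test_empty_diagnoses_all_zero(self):
        patients = [Patient("P1", Sex.MALE, "RP", PedigreePattern.AR)]
        r = reclassify_cohort([], patients)
        assert r.crosstab.values.sum() == 0 and r.n_definite == 0

    def test_diagnosis_change_counted(self):
        patients = [Patient("P1", Sex.MALE, "RP", PedigreePattern.AR)]
        r = reclassify_cohort([self._dx("P1", Mode.AR, refined="Usher")], patients)
        assert r.n_diagnosis_changed == 1
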