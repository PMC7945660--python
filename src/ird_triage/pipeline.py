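"""End-to-end orchestration: QC -> panel -> classification -> diagnosis -> summary."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .cohort_summary import CohortSummary, summarize
from .diagnosis_engine import (
    Candidate,
    CompatibilityMap,
    diagnose_patient,
    load_compatibility,
    rank_gene_diagnoses,
)
from .io_model import (
    Cohort,
    DiagnosisStatus,
    MolecularDiagnosis,
    Patient,
    Sex,
    VariantCall,
    VariantKey,
    read_annotations,
    read_patients,
    read_panel,
    read_vcf,
)
from .variant_triage import (
    PathogenicityCall,
    QcThresholds,
    apply_qc_filter,
    classify_pathogenicity,
    flag_for_validation,
    restrict_to_panel,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the triage pipeline, loadable from YAML."""

    min_depth: int = 10
    min_vaf: float = 0.10
    min_alt_reads: int = 2
    consensus_denominator: Literal["fixed6", "available"] = "fixed6"
    validation_min_coverage: int = 20
    xl_het_female: Literal["carrier", "affected"] = "carrier"
    infer_hemizygous_x: bool = True
    compatibility_mode: Literal["and", "or"] = "and"
    denominator: Literal["refined", "clinical"] = "refined"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @property
    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(self.min_depth, self.min_vaf, self.min_alt_reads)


@dataclass
class PipelineResult:
    diagnoses: list[MolecularDiagnosis]
    summary: CohortSummary
    runners_up: dict[str, list[MolecularDiagnosis]]
    validation_flags: list[VariantKey]
    n_calls_input: int
    n_calls_qc_removed: int
    n_pathogenic_calls: int


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full triage on an in-memory cohort."""
    config = config or PipelineConfig()
    compat = load_compatibility()
    panel_map = cohort.panel_map
    thresholds = config.qc_thresholds
    by_patient = cohort.calls_by_patient()

    diagnoses: list[MolecularDiagnosis] = []
    runners_up: dict[str, list[MolecularDiagnosis]] = {}
    pathogenic_calls: list[VariantCall] = []
    n_input = 0
    n_removed = 0
    for patient in sorted(cohort.patients, key=lambda p: p.patient_id):
        calls = by_patient[patient.patient_id]
        n_input += len(calls)
        kept = apply_qc_filter(calls, thresholds)
        n_removed += len(calls) - len(kept)
        pairs = restrict_to_panel(kept, cohort.annotations, panel_map)
        candidates = []
        for call, ann in pairs:
            patho = classify_pathogenicity(ann, config.consensus_denominator)
            if patho.pathogenic:
                candidates.append(Candidate(call, ann, patho))
                pathogenic_calls.append(call)
        from .diagnosis_engine import phenotype_inheritance_filter

        filtered = phenotype_inheritance_filter(
            candidates, patient, panel_map, compat, config.compatibility_mode
        )
        ranked = rank_gene_diagnoses(
            patient, filtered, panel_map, compat, config.xl_het_female
        )
        if ranked:
            diagnoses.append(ranked[0])
            if len(ranked) > 1:
                runners_up[patient.patient_id] = ranked[1:]
        else:
            diagnoses.append(
                MolecularDiagnosis(
                    patient_id=patient.patient_id,
                    status=DiagnosisStatus.NONE,
                    gene=None,
                    causal_variants=(),
                    mode=None,
                    refined_inheritance=None,
                    refined_diagnosis=patient.clinical_diagnosis,
                )
            )

    summary = summarize(diagnoses, cohort.patients, config.denominator)
    flags = flag_for_validation(pathogenic_calls, config.validation_min_coverage)
    return PipelineResult(
        diagnoses=diagnoses,
        summary=summary,
        runners_up=runners_up,
        validation_flags=flags,
        n_calls_input=n_input,
        n_calls_qc_removed=n_removed,
        n_pathogenic_calls=len(pathogenic_calls),
    )


def load_cohort(
    vcf_dir: str | Path,
    annotations_path: str | Path,
    panel_path: str | Path,
    patients_path: str | Path,
    infer_hemizygous_x: bool = True,
) -> Cohort:
    """Assemble a cohort from files: one ``<patient_id>.vcf`` per patient.

    The male-X hemizygosity inference is applied only to male patients
    (sex comes from the patient table, not the VCF).
    """
    vcf_dir = Path(vcf_dir)
    patients = read_patients(patients_path)
    panel = read_panel(panel_path)
    annotations = read_annotations(annotations_path)
    calls: list[VariantCall] = []
    for patient in patients:
        path = vcf_dir / f"{patient.patient_id}.vcf"
        infer = infer_hemizygous_x and patient.sex is Sex.MALE
        calls.extend(read_vcf(path, patient.patient_id, infer_hemizygous_x=infer))
    return Cohort(patients=patients, calls=calls, annotations=annotations, panel=panel)
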