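"""Per-patient molecular diagnosis under Mendelian inheritance rules.

A patient receives a *definite* diagnosis when

* one pathogenic variant lies in a gene with autosomal-dominant (AD)
  inheritance, or a hemizygous (male) / homozygous (female) pathogenic
  variant lies in an X-linked (XL) gene, or
* two distinct heterozygous pathogenic variants (assumed in trans; no
  parental genotypes are used) or one homozygous pathogenic variant lie in
  an autosomal-recessive (AR) gene;

a *possible* diagnosis when exactly one heterozygous pathogenic variant is
found in an AR gene; and *none* otherwise.  Before diagnosis, candidates
incompatible with the patient's phenotype or pedigree inheritance pattern
are excluded.  Simplex pedigrees (single affected individual) exclude
nothing on mode — such cases may resolve to AD, AR or XL.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml

from .io_model import (
    CausalVariant,
    DiagnosisStatus,
    MolecularDiagnosis,
    Mode,
    PanelGene,
    Patient,
    PedigreePattern,
    Sex,
    VariantAnnotation,
    VariantCall,
    Zygosity,
    _data_path,
)
from .variant_triage import PathogenicityCall

logger = logging.getLogger(__name__)

#: Reporting-strength weight of each satisfied pathogenicity criterion,
#: used only for deterministic tie-breaking between qualifying genes.
RATIONALE_WEIGHT = {"KNOWN": 3, "ACMG": 2, "TRUNCATING": 2, "CONSENSUS": 1}

_STATUS_RANK = {
    DiagnosisStatus.DEFINITE: 2,
    DiagnosisStatus.POSSIBLE: 1,
    DiagnosisStatus.NONE: 0,
}


@dataclass(frozen=True)
class Candidate:
    """One pathogenic variant call with its annotation, pre-diagnosis."""

    call: VariantCall
    annotation: VariantAnnotation
    pathogenicity: PathogenicityCall


@dataclass(frozen=True)
class CompatibilityMap:
    """Many-to-many phenotype compatibility plus a specificity ordering.

    ``compatible`` maps a clinical diagnosis label to the set of gene
    phenotype-group labels it is compatible with (e.g. retinitis pigmentosa
    is compatible with choroideraemia and Bietti crystalline dystrophy genes,
    which clinically mimic RP).  ``specificity`` orders phenotype labels from
    most to least specific and is used when a diagnostic gene forces a
    revision of the clinical diagnosis.
    """

    compatible: Mapping[str, frozenset[str]]
    specificity: tuple[str, ...]

    def compatible_with(self, clinical_diagnosis: str) -> frozenset[str]:
        return self.compatible.get(clinical_diagnosis, frozenset({clinical_diagnosis}))

    def most_specific(self, groups: frozenset[str]) -> str:
        order = {label: i for i, label in enumerate(self.specificity)}
        return min(sorted(groups), key=lambda g: order.get(g, len(order)))


def load_compatibility(path: str | Path | None = None) -> CompatibilityMap:
    """Load the shipped (editable) phenotype-compatibility configuration."""
    path = Path(path) if path else _data_path("phenotype_compatibility.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CompatibilityMap(
        compatible={k: frozenset(v) for k, v in raw["compatible"].items()},
        specificity=tuple(raw["specificity"]),
    )


def phenotype_inheritance_filter(
    candidates: Sequence[Candidate],
    patient: Patient,
    panel_map: Mapping[str, PanelGene],
    compat: CompatibilityMap | None = None,
    mode: Literal["and", "or"] = "and",
) -> list[Candidate]:
    """Exclude candidates incompatible with the patient's phenotype/pedigree.

    A candidate survives when (a) its gene's phenotype groups intersect the
    patient's compatible-phenotype set AND (b) if the pedigree pattern is AD
    or XL, the gene carries that mode.  AR and simplex pedigrees exclude
    nothing on mode.  ``mode="or"`` relaxes the conjunction to a disjunction
    (sensitivity analysis for the ambiguous "phenotypes or inheritance
    patterns" exclusion wording).
    """
    compat = compat or load_compatibility()
    compatible_groups = compat.compatible_with(patient.clinical_diagnosis)
    kept: list[Candidate] = []
    for cand in candidates:
        gene = panel_map.get(cand.annotation.gene.upper())
        if gene is None:
            raise KeyError(f"gene {cand.annotation.gene} not on panel")
        pheno_ok = bool(gene.phenotype_groups & compatible_groups)
        if patient.pedigree_pattern in (PedigreePattern.AD, PedigreePattern.XL):
            mode_ok = Mode(patient.pedigree_pattern.value) in gene.modes
        else:
            mode_ok = True
        keep = (pheno_ok and mode_ok) if mode == "and" else (pheno_ok or mode_ok)
        if keep:
            kept.append(cand)
    return kept


def _causal(cand: Candidate) -> CausalVariant:
    return CausalVariant(
        chrom=cand.call.chrom,
        pos=cand.call.pos,
        ref=cand.call.ref,
        alt=cand.call.alt,
        zygosity=cand.call.zygosity,
        consequence=cand.annotation.consequence,
        previously_reported=cand.annotation.previously_reported,
        rationale=cand.pathogenicity.rationale,
    )


def _weight(cand: Candidate) -> int:
    return sum(RATIONALE_WEIGHT[c] for c in cand.pathogenicity.rationale)


def _best_first(cands: list[Candidate]) -> list[Candidate]:
    return sorted(cands, key=lambda c: (-_weight(c), c.call.key))


@dataclass(frozen=True)
class _GeneOption:
    status: DiagnosisStatus
    mode: Mode
    causal: tuple[Candidate, ...]

    @property
    def score(self) -> int:
        return sum(_weight(c) for c in self.causal)


def _gene_options(
    patient: Patient,
    gene: PanelGene,
    cands: list[Candidate],
    xl_het_female: Literal["carrier", "affected"],
) -> list[_GeneOption]:
    # Two het calls at the same locus are one allele: collapse by variant key.
    by_key: dict = {}
    for c in cands:
        prev = by_key.get(c.call.key)
        if prev is None or _weight(c) > _weight(prev):
            by_key[c.call.key] = c
    unique = list(by_key.values())
    hets = _best_first([c for c in unique if c.call.zygosity is Zygosity.HET])
    homs = _best_first([c for c in unique if c.call.zygosity is Zygosity.HOM])
    hemis = _best_first([c for c in unique if c.call.zygosity is Zygosity.HEMI])

    options: list[_GeneOption] = []

    # AD: a single pathogenic variant suffices.  For dual-mode (AD+AR) genes
    # the AD rule fires only under an AD pedigree, so that compound
    # heterozygotes in dual-mode genes resolve as AR rather than every
    # single het auto-resolving as definite AD.
    ad_applicable = Mode.AD in gene.modes and (
        gene.modes == frozenset({Mode.AD})
        or patient.pedigree_pattern is PedigreePattern.AD
    )
    if ad_applicable and unique:
        best = _best_first(unique)[0]
        options.append(_GeneOption(DiagnosisStatus.DEFINITE, Mode.AD, (best,)))

    if Mode.XL in gene.modes:
        if patient.sex is Sex.MALE and hemis:
            options.append(_GeneOption(DiagnosisStatus.DEFINITE, Mode.XL, (hemis[0],)))
        if patient.sex is Sex.FEMALE:
            if homs:
                options.append(
                    _GeneOption(DiagnosisStatus.DEFINITE, Mode.XL, (homs[0],))
                )
            elif hets and xl_het_female == "affected":
                options.append(
                    _GeneOption(DiagnosisStatus.DEFINITE, Mode.XL, (hets[0],))
                )

    if Mode.AR in gene.modes:
        if homs:
            options.append(_GeneOption(DiagnosisStatus.DEFINITE, Mode.AR, (homs[0],)))
        if len(hets) >= 2:
            options.append(
                _GeneOption(DiagnosisStatus.DEFINITE, Mode.AR, tuple(hets[:2]))
            )
        elif len(hets) == 1 and not homs:
            options.append(
                _GeneOption(DiagnosisStatus.POSSIBLE, Mode.AR, (hets[0],))
            )
    return options


def _refine_diagnosis(
    patient: Patient, gene: PanelGene, compat: CompatibilityMap
) -> str:
    """Clinical diagnosis after the genetic finding.

    If the diagnostic gene's phenotype groups include the presenting clinical
    diagnosis it is kept; otherwise the gene forces a revision to its most
    specific phenotype group (e.g. an RP presentation with causal CHM
    variants is redefined as choroideraemia).
    """
    if patient.clinical_diagnosis in gene.phenotype_groups:
        return patient.clinical_diagnosis
    return compat.most_specific(gene.phenotype_groups)


def diagnose_patient(
    patient: Patient,
    candidates: Sequence[Candidate],
    panel_map: Mapping[str, PanelGene],
    compat: CompatibilityMap | None = None,
    xl_het_female: Literal["carrier", "affected"] = "carrier",
) -> MolecularDiagnosis:
    """Determine the patient's molecular diagnosis from filtered candidates.

    The best status across genes wins (definite > possible > none); ties are
    broken by the summed rationale-strength score of the causal variants,
    then alphabetically by gene symbol.
    """
    ranked = rank_gene_diagnoses(patient, candidates, panel_map, compat, xl_het_female)
    if not ranked:
        return MolecularDiagnosis(
            patient_id=patient.patient_id,
            status=DiagnosisStatus.NONE,
            gene=None,
            causal_variants=(),
            mode=None,
            refined_inheritance=None,
            refined_diagnosis=patient.clinical_diagnosis,
        )
    return ranked[0]


def rank_gene_diagnoses(
    patient: Patient,
    candidates: Sequence[Candidate],
    panel_map: Mapping[str, PanelGene],
    compat: CompatibilityMap | None = None,
    xl_het_female: Literal["carrier", "affected"] = "carrier",
) -> list[MolecularDiagnosis]:
    """All per-gene diagnoses, best first (winner plus runners-up)."""
    compat = compat or load_compatibility()
    by_gene: dict[str, list[Candidate]] = {}
    for cand in candidates:
        symbol = cand.annotation.gene.upper()
        if symbol not in panel_map:
            raise KeyError(
                f"gene {cand.annotation.gene} not on panel "
                "(candidates must be panel-restricted before diagnosis)"
            )
        by_gene.setdefault(symbol, []).append(cand)

    scored: list[tuple[int, int, str, _GeneOption]] = []
    for symbol in sorted(by_gene):
        gene = panel_map[symbol]
        options = _gene_options(patient, gene, by_gene[symbol], xl_het_female)
        if not options:
            continue
        best = max(options, key=lambda o: (_STATUS_RANK[o.status], o.score))
        scored.append((_STATUS_RANK[best.status], best.score, symbol, best))

    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    out: list[MolecularDiagnosis] = []
    for _, _, symbol, option in scored:
        gene = panel_map[symbol]
        definite = option.status is DiagnosisStatus.DEFINITE
        out.append(
            MolecularDiagnosis(
                patient_id=patient.patient_id,
                status=option.status,
                gene=symbol,
                causal_variants=tuple(_causal(c) for c in option.causal),
                mode=option.mode,
                refined_inheritance=option.mode if definite else None,
                refined_diagnosis=_refine_diagnosis(patient, gene, compat)
                if definite
                else patient.clinical_diagnosis,
            )
        )
    return out


@dataclass
class Reclassification:
    """Cross-tabulation of pedigree-based vs genetically refined inheritance."""

    crosstab: pd.DataFrame  # rows: pedigree_pattern, cols: refined mode
    n_definite: int
    n_inheritance_redefined: int  # definite patients with pedigree != refined mode
    n_diagnosis_changed: int  # definite patients whose clinical diagnosis changed
    n_simplex: int
    simplex_by_mode: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "crosstab": {
                str(row): {str(col): int(v) for col, v in series.items()}
                for row, series in self.crosstab.iterrows()
            },
            "n_definite": self.n_definite,
            "n_inheritance_redefined": self.n_inheritance_redefined,
            "n_diagnosis_changed": self.n_diagnosis_changed,
            "n_simplex": self.n_simplex,
            "simplex_by_mode": dict(self.simplex_by_mode),
        }


def reclassify_cohort(
    diagnoses: Sequence[MolecularDiagnosis], patients: Sequence[Patient]
) -> Reclassification:
    """Tabulate inheritance reclassification among definitely diagnosed patients.

    A patient counts as redefined when the pedigree pattern differs from the
    genetically refined mode; every solved simplex case is redefined by
    construction.
    """
    by_id = {p.patient_id: p for p in patients}
    rows = []
    n_changed = 0
    for d in diagnoses:
        if d.status is not DiagnosisStatus.DEFINITE:
            continue
        p = by_id[d.patient_id]
        rows.append(
            {
                "pedigree": p.pedigree_pattern.value,
                "refined": d.refined_inheritance.value,
            }
        )
        if d.refined_diagnosis != p.clinical_diagnosis:
            n_changed += 1
    pedigree_order = [m.value for m in PedigreePattern]
    mode_order = [m.value for m in Mode]
    if rows:
        df = pd.DataFrame(rows)
        ct = pd.crosstab(df["pedigree"], df["refined"])
    else:
        ct = pd.DataFrame()
    ct = ct.reindex(index=pedigree_order, columns=mode_order, fill_value=0).fillna(0)
    ct = ct.astype(int)
    ct.index.name = "pedigree"
    ct.columns.name = "refined"
    n_def = int(ct.values.sum())
    redefined = sum(
        int(ct.loc[ped, mode])
        for ped in pedigree_order
        for mode in mode_order
        if ped != mode
    )
    simplex = ct.loc[PedigreePattern.SIMPLEX.value]
    return Reclassification(
        crosstab=ct,
        n_definite=n_def,
        n_inheritance_redefined=redefined,
        n_diagnosis_changed=n_changed,
        n_simplex=int(simplex.sum()),
        simplex_by_mode={m: int(simplex[m]) for m in mode_order},
    )
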