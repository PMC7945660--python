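"""Synthetic cohorts with planted ground truth for closed-loop testing.

The generator emits exactly the file formats the pipeline readers consume —
per-patient VCFs, an annotation table, a gene panel, a patient table — plus
a truth table recording each patient's intended diagnosis (status, gene,
mode).  Causal genotypes are planted per inheritance pattern (AD het, AR
compound het, AR hom, AR single het for "possible", XL hemizygous male, XL
homozygous female) and are guaranteed to pass quality control and the
pathogenicity rules unless noise knobs explicitly degrade them; background
variants are guaranteed benign under all four classification criteria.

Variant loci live on a toy exome coordinate system (each gene owns a
disjoint window on a synthetic contig; X-linked genes sit on chrX); HGVS
strings are schematic but format-valid.

The ``paper_counts_plan`` preset encodes a fixed 168-patient reference
cohort whose phenotype strata, gene spectrum, allele consequence/novelty
mix and pedigree structure are pinned exactly, so every cohort-level
percentage the pipeline reports is reproducible end to end from files.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AcmgClass,
    Cohort,
    Consequence,
    Mode,
    PanelGene,
    Patient,
    PedigreePattern,
    PREDICTOR_TOOLS,
    Sex,
    VariantAnnotation,
    VariantCall,
    VariantKey,
    Verdict,
    _data_path,
    read_panel,
    write_annotations,
    write_panel,
    write_patients,
)


class PlantPattern(str, enum.Enum):
    """Planted causal-genotype pattern for one patient."""

    AD_HET = "AD-het"
    AR_COMPOUND_HET = "AR-compound-het"
    AR_HOM = "AR-hom"
    AR_SINGLE_HET = "AR-single-het"
    XL_HEMI = "XL-hemi"
    XL_HOM = "XL-hom-female"
    NONE = "none"


#: Expected pipeline outcome (status, mode) for each planted pattern.
PATTERN_TRUTH: dict[PlantPattern, tuple[str, str | None]] = {
    PlantPattern.AD_HET: ("definite", "AD"),
    PlantPattern.AR_COMPOUND_HET: ("definite", "AR"),
    PlantPattern.AR_HOM: ("definite", "AR"),
    PlantPattern.AR_SINGLE_HET: ("possible", "AR"),
    PlantPattern.XL_HEMI: ("definite", "XL"),
    PlantPattern.XL_HOM: ("definite", "XL"),
    PlantPattern.NONE: ("none", None),
}

_PATTERN_MODE = {
    PlantPattern.AD_HET: Mode.AD,
    PlantPattern.AR_COMPOUND_HET: Mode.AR,
    PlantPattern.AR_HOM: Mode.AR,
    PlantPattern.AR_SINGLE_HET: Mode.AR,
    PlantPattern.XL_HEMI: Mode.XL,
    PlantPattern.XL_HOM: Mode.XL,
}


@dataclass(frozen=True)
class PatientPlan:
    patient_id: str
    sex: Sex
    clinical_diagnosis: str
    pedigree_pattern: PedigreePattern
    pattern: PlantPattern
    gene: str | None  # None iff pattern is NONE


@dataclass(frozen=True)
class AllelePlan:
    """Exact consequence/novelty quotas over the planted causal variants.

    Applies to the single-count variants of definite diagnoses (homozygous
    planted variants get the fixed ``hom_*`` attributes and count two allele
    copies downstream).  Quota sums must match the number of such variants.
    """

    consequence_counts: Mapping[Consequence, int]
    reported_count: int
    hom_consequence: Consequence = Consequence.MISSENSE
    hom_reported: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    plans: tuple[PatientPlan, ...]
    rng_seed: int = 0
    background_mean: float = 6.0  # mean benign variants per patient (Poisson)
    bg_qc_fail_rate: float = 0.10  # fraction of background calls below QC
    causal_qc_fail_rate: float = 0.0
    second_allele_dropout: float = 0.0  # QC-kill the 2nd compound-het allele
    drop_known_rate: float = 0.0
    drop_acmg_rate: float = 0.0
    drop_consensus_rate: float = 0.0
    allele_plan: AllelePlan | None = None
    consequence_mix: Mapping[Consequence, float] = field(
        default_factory=lambda: {
            Consequence.MISSENSE: 0.60,
            Consequence.NONSENSE: 0.18,
            Consequence.FRAMESHIFT_INSERTION: 0.09,
            Consequence.FRAMESHIFT_DELETION: 0.08,
            Consequence.SPLICING: 0.05,
        }
    )
    reported_rate: float = 0.65

    def __post_init__(self) -> None:
        for name in (
            "bg_qc_fail_rate", "causal_qc_fail_rate", "second_allele_dropout",
            "drop_known_rate", "drop_acmg_rate", "drop_consensus_rate",
            "reported_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


def ird_panel() -> list[PanelGene]:
    """The shipped demonstration IRD gene panel."""
    return read_panel(_data_path("panel_ird.tsv"))


# ---------------------------------------------------------------------------
# Toy exome coordinates
# ---------------------------------------------------------------------------

_OFFPANEL_GENES = ("TTN", "OBSCN", "MUC16", "NEB", "SYNE1")


class _GenePlacer:
    """Assigns each gene a disjoint coordinate window and hands out loci."""

    def __init__(self, panel: Sequence[PanelGene]):
        self._window: dict[str, tuple[str, int]] = {}
        self._counter: dict[str, int] = {}
        idx = 0
        for g in sorted(panel, key=lambda g: g.symbol):
            chrom = "chrX" if Mode.XL in g.modes else f"chr{(idx % 22) + 1}"
            self._window[g.symbol] = (chrom, 1_000_000 + idx * 50_000)
            idx += 1
        for sym in _OFFPANEL_GENES:
            self._window[sym] = (f"chr{(idx % 22) + 1}", 1_000_000 + idx * 50_000)
            idx += 1

    def next_locus(self, gene: str) -> tuple[str, int]:
        chrom, base = self._window[gene]
        n = self._counter.get(gene, 0)
        self._counter[gene] = n + 1
        return chrom, base + 3 * n + 1


_CONSEQ_ALLELES = {
    Consequence.MISSENSE: ("A", "G"),
    Consequence.NONSENSE: ("C", "T"),
    Consequence.SPLICING: ("G", "A"),
    Consequence.SYNONYMOUS: ("T", "C"),
    Consequence.OTHER: ("G", "C"),
    Consequence.FRAMESHIFT_INSERTION: ("A", "AT"),
    Consequence.FRAMESHIFT_DELETION: ("AT", "A"),
}


def _hgvs(consequence: Consequence, offset: int) -> tuple[str, str]:
    n = offset + 100
    aa = n // 3 + 1
    if consequence is Consequence.MISSENSE:
        return f"c.{n}A>G", f"p.(Arg{aa}Gly)"
    if consequence is Consequence.NONSENSE:
        return f"c.{n}C>T", f"p.(Arg{aa}*)"
    if consequence is Consequence.SPLICING:
        return f"c.{n}+1G>A", "."
    if consequence is Consequence.FRAMESHIFT_INSERTION:
        return f"c.{n}dupT", f"p.(Leu{aa}fs)"
    if consequence is Consequence.FRAMESHIFT_DELETION:
        return f"c.{n}delT", f"p.(Leu{aa}fs)"
    if consequence is Consequence.SYNONYMOUS:
        return f"c.{n}T>C", f"p.(Leu{aa}=)"
    return f"c.{n}G>C", "p.?"


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def _tool_verdicts(n_damaging: int, rng: np.random.Generator) -> dict[str, Verdict]:
    order = list(PREDICTOR_TOOLS)
    idx = rng.permutation(len(order))
    verdicts = {}
    for rank, i in enumerate(idx):
        verdicts[order[i]] = Verdict.DAMAGING if rank < n_damaging else Verdict.TOLERATED
    return verdicts


def _degrade_call(call: VariantCall) -> VariantCall:
    # depth 8 < 10 and alt reads 1 < 2: fails QC under the default thresholds
    return replace(call, total_depth=8, alt_depth=1, vaf=1 / 8)


@dataclass
class _CausalSpec:
    plan: PatientPlan
    zygosity: str  # "het" | "hom" | "hemi"
    is_second_allele: bool


def build_cohort(
    config: SimulationConfig, panel: Sequence[PanelGene] | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Build an in-memory cohort plus its truth table, deterministically."""
    from .io_model import Zygosity  # local alias

    panel = list(panel) if panel is not None else ird_panel()
    panel_map = {g.symbol: g for g in panel}
    for plan in config.plans:
        if plan.pattern is PlantPattern.NONE:
            continue
        gene = panel_map.get(plan.gene or "")
        if gene is None:
            raise ValueError(f"planted gene {plan.gene} absent from panel")
        if _PATTERN_MODE[plan.pattern] not in gene.modes:
            raise ValueError(
                f"planted mode {_PATTERN_MODE[plan.pattern].value} absent from "
                f"panel entry for {plan.gene}"
            )

    rng = np.random.default_rng(config.rng_seed)
    placer = _GenePlacer(panel)

    # --- causal variant slots, in plan order -----------------------------
    slots: list[_CausalSpec] = []
    for plan in config.plans:
        if plan.pattern is PlantPattern.NONE:
            continue
        if plan.pattern is PlantPattern.AR_COMPOUND_HET:
            slots.append(_CausalSpec(plan, "het", False))
            slots.append(_CausalSpec(plan, "het", True))
        elif plan.pattern in (PlantPattern.AD_HET, PlantPattern.AR_SINGLE_HET):
            slots.append(_CausalSpec(plan, "het", False))
        elif plan.pattern is PlantPattern.AR_HOM:
            slots.append(_CausalSpec(plan, "hom", False))
        elif plan.pattern is PlantPattern.XL_HEMI:
            slots.append(_CausalSpec(plan, "hemi", False))
        elif plan.pattern is PlantPattern.XL_HOM:
            slots.append(_CausalSpec(plan, "hom", False))

    definite_patterns = {
        PlantPattern.AD_HET, PlantPattern.AR_COMPOUND_HET, PlantPattern.AR_HOM,
        PlantPattern.XL_HEMI, PlantPattern.XL_HOM,
    }
    quota_slots = [
        s for s in slots
        if s.plan.pattern in definite_patterns and s.zygosity != "hom"
    ]

    # --- consequence / novelty assignment --------------------------------
    attrs: dict[int, tuple[Consequence, bool]] = {}
    if config.allele_plan is not None:
        ap = config.allele_plan
        deck_cons: list[Consequence] = []
        for cons, n in ap.consequence_counts.items():
            deck_cons.extend([Consequence(cons)] * n)
        if len(deck_cons) != len(quota_slots):
            raise ValueError(
                f"allele plan covers {len(deck_cons)} variants but the plans "
                f"contain {len(quota_slots)} quota-eligible causal variants"
            )
        if not 0 <= ap.reported_count <= len(deck_cons):
            raise ValueError("reported_count out of range")
        deck_rep = [True] * ap.reported_count + [False] * (
            len(deck_cons) - ap.reported_count
        )
        rng.shuffle(deck_cons)
        rng.shuffle(deck_rep)
        it = iter(zip(deck_cons, deck_rep))
        for i, s in enumerate(slots):
            if s.plan.pattern in definite_patterns and s.zygosity != "hom":
                attrs[i] = next(it)
            elif s.zygosity == "hom" and s.plan.pattern in definite_patterns:
                attrs[i] = (ap.hom_consequence, ap.hom_reported)
            else:  # possible-diagnosis single het
                attrs[i] = (Consequence.MISSENSE, bool(rng.random() < 0.5))
    else:
        cons_labels = list(config.consequence_mix)
        probs = np.array([config.consequence_mix[c] for c in cons_labels], float)
        probs = probs / probs.sum()
        for i, s in enumerate(slots):
            cons = cons_labels[int(rng.choice(len(cons_labels), p=probs))]
            attrs[i] = (Consequence(cons), bool(rng.random() < config.reported_rate))

    # --- materialise calls and annotations -------------------------------
    calls: list[VariantCall] = []
    annotations: dict[VariantKey, VariantAnnotation] = {}

    def _add_annotation(
        chrom: str, pos: int, ref: str, alt: str, gene: str,
        consequence: Consequence, reported: bool, pathogenic: bool,
        offset: int,
    ) -> None:
        if pathogenic:
            known = reported and not (rng.random() < config.drop_known_rate)
            if rng.random() < config.drop_acmg_rate:
                acmg = AcmgClass.UNCERTAIN
            else:
                acmg = AcmgClass.PATHOGENIC if reported else AcmgClass.LIKELY_PATHOGENIC
            n_damaging = 2 if rng.random() < config.drop_consensus_rate else 5
        else:
            known = False
            acmg = [AcmgClass.UNCERTAIN, AcmgClass.LIKELY_BENIGN, AcmgClass.BENIGN][
                int(rng.integers(3))
            ]
            n_damaging = int(rng.integers(0, 4))  # at most 3 of 6: no consensus
        hgvs_c, hgvs_p = _hgvs(consequence, offset)
        ann = VariantAnnotation(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            consequence=consequence, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            known_disease_causing=known, acmg_class=acmg,
            predictor_verdicts=_tool_verdicts(n_damaging, rng),
            previously_reported=reported,
        )
        annotations[ann.key] = ann

    def _make_call(
        plan: PatientPlan, chrom: str, pos: int, ref: str, alt: str, zyg: str
    ) -> VariantCall:
        depth = int(rng.integers(30, 81))
        if zyg == "het":
            alt_depth = int(round(depth * rng.uniform(0.40, 0.60)))
        else:
            alt_depth = depth
        return VariantCall(
            patient_id=plan.patient_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            zygosity=Zygosity(zyg), total_depth=depth, alt_depth=alt_depth,
            vaf=alt_depth / depth,
        )

    for i, s in enumerate(slots):
        consequence, reported = attrs[i]
        chrom, pos = placer.next_locus(s.plan.gene)
        ref, alt = _CONSEQ_ALLELES[consequence]
        _add_annotation(
            chrom, pos, ref, alt, s.plan.gene, consequence, reported,
            pathogenic=True, offset=pos % 997,
        )
        call = _make_call(s.plan, chrom, pos, ref, alt, s.zygosity)
        degrade = rng.random() < config.causal_qc_fail_rate or (
            s.is_second_allele and rng.random() < config.second_allele_dropout
        )
        if degrade:
            call = _degrade_call(call)
        calls.append(call)

    # --- benign background variants --------------------------------------
    bg_pool = sorted(panel_map) + list(_OFFPANEL_GENES)
    for plan in config.plans:
        n_bg = int(rng.poisson(config.background_mean))
        for _ in range(n_bg):
            gene = bg_pool[int(rng.integers(len(bg_pool)))]
            consequence = [
                Consequence.SYNONYMOUS, Consequence.MISSENSE, Consequence.OTHER
            ][int(rng.choice(3, p=[0.4, 0.5, 0.1]))]
            reported = bool(rng.random() < 0.3)
            chrom, pos = placer.next_locus(gene)
            ref, alt = _CONSEQ_ALLELES[consequence]
            _add_annotation(
                chrom, pos, ref, alt, gene, consequence, reported,
                pathogenic=False, offset=pos % 997,
            )
            zyg = "hom" if rng.random() < 0.1 else "het"
            call = _make_call(plan, chrom, pos, ref, alt, zyg)
            if rng.random() < config.bg_qc_fail_rate:
                call = _degrade_call(call)
            calls.append(call)

    patients = [
        Patient(
            patient_id=p.patient_id, sex=p.sex,
            clinical_diagnosis=p.clinical_diagnosis,
            pedigree_pattern=p.pedigree_pattern,
        )
        for p in config.plans
    ]
    truth = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "true_status": PATTERN_TRUTH[p.pattern][0],
                "true_gene": p.gene or "",
                "true_mode": PATTERN_TRUTH[p.pattern][1] or "",
                "pattern": p.pattern.value,
            }
            for p in config.plans
        ]
    )
    cohort = Cohort(
        patients=patients, calls=calls, annotations=annotations, panel=panel
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23}


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write one patient's calls as a minimal, deterministic VCF 4.2 file."""
    ordered = sorted(calls, key=lambda c: (_CHROM_ORDER.get(c.chrom, 99), c.pos, c.alt))
    contigs = sorted(
        {c.chrom for c in ordered}, key=lambda ch: _CHROM_ORDER.get(ch, 99)
    )
    sample = ordered[0].patient_id if ordered else "SAMPLE"
    gt_of = {"het": "0/1", "hom": "1/1", "hemi": "1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in contigs:
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
            '"Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for c in ordered:
            ref_depth = c.total_depth - c.alt_depth
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t.\t"
                f"GT:DP:AD\t{gt_of[c.zygosity.value]}:{c.total_depth}:"
                f"{ref_depth},{c.alt_depth}\n"
            )


def simulate_cohort(
    config: SimulationConfig,
    panel: Sequence[PanelGene] | None = None,
    out_dir: str | Path = ".",
) -> tuple[Cohort, pd.DataFrame]:
    """Build a cohort and write all pipeline input files plus truth.tsv.

    Outputs under ``out_dir``: ``vcf/<patient_id>.vcf`` per patient,
    ``annotations.tsv``, ``panel.tsv``, ``patients.tsv``, ``truth.tsv``.
    Byte-identical across runs with the same config (incl. rng_seed).
    """
    out_dir = Path(out_dir)
    (out_dir / "vcf").mkdir(parents=True, exist_ok=True)
    cohort, truth = build_cohort(config, panel)
    by_patient = cohort.calls_by_patient()
    for patient in cohort.patients:
        write_vcf(by_patient[patient.patient_id], out_dir / "vcf" / f"{patient.patient_id}.vcf")
    write_annotations(cohort.annotations, out_dir / "annotations.tsv")
    write_panel(cohort.panel, out_dir / "panel.tsv")
    write_patients(cohort.patients, out_dir / "patients.tsv")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return cohort, truth


# ---------------------------------------------------------------------------
# Coverage simulation (feeds capture_qc)
# ---------------------------------------------------------------------------

def simulate_coverage(
    target_size: int,
    shape: str,
    params: Mapping[str, float] | None = None,
    rng_seed: int = 0,
):
    """Simulate a per-base coverage profile over a capture target.

    Shapes: ``uniform`` (constant ``depth``), ``bimodal`` (``low``/``high``
    with ``frac_high`` of bases high), ``lognormal`` (``mean``/``sigma`` of
    the underlying normal).
    """
    from .capture_qc import CoverageProfile

    if target_size <= 0:
        raise ValueError("target_size must be positive")
    params = dict(params or {})
    rng = np.random.default_rng(rng_seed)
    if shape == "uniform":
        depth = int(params.get("depth", 30))
        depths = np.full(target_size, depth)
    elif shape == "bimodal":
        low = int(params.get("low", 0))
        high = int(params.get("high", 60))
        frac_high = float(params.get("frac_high", 0.5))
        n_high = int(round(target_size * frac_high))
        depths = np.concatenate(
            [np.full(n_high, high), np.full(target_size - n_high, low)]
        )
        rng.shuffle(depths)
    elif shape == "lognormal":
        mean = float(params.get("mean", 3.4))
        sigma = float(params.get("sigma", 0.5))
        depths = np.round(rng.lognormal(mean, sigma, size=target_size)).astype(int)
    else:
        raise ValueError(f"unknown coverage shape {shape!r}")
    return CoverageProfile(depths)


# ---------------------------------------------------------------------------
# Plan builders
# ---------------------------------------------------------------------------

def uniform_plan(
    pattern_counts: Mapping[PlantPattern, int],
    gene_by_pattern: Mapping[PlantPattern, str] | None = None,
    clinical_diagnosis: str = "RP",
    pedigree: PedigreePattern = PedigreePattern.SIMPLEX,
) -> tuple[PatientPlan, ...]:
    """A homogeneous plan: n patients per pattern, one gene per pattern.

    XL patterns get the sexes their genotypes require (hemizygous male,
    homozygous female).  Useful for recovery/degradation experiments.
    """
    default_genes = {
        PlantPattern.AD_HET: "RHO",
        PlantPattern.AR_COMPOUND_HET: "USH2A",
        PlantPattern.AR_HOM: "EYS",
        PlantPattern.AR_SINGLE_HET: "ABCA4",
        PlantPattern.XL_HEMI: "RPGR",
        PlantPattern.XL_HOM: "RP2",
        PlantPattern.NONE: None,
    }
    genes = dict(default_genes) | dict(gene_by_pattern or {})
    plans: list[PatientPlan] = []
    i = 0
    for pattern, n in pattern_counts.items():
        for _ in range(n):
            i += 1
            if pattern is PlantPattern.XL_HEMI:
                sex = Sex.MALE
            elif pattern is PlantPattern.XL_HOM:
                sex = Sex.FEMALE
            else:
                sex = Sex.MALE if i % 2 else Sex.FEMALE
            plans.append(
                PatientPlan(
                    patient_id=f"S{i:04d}",
                    sex=sex,
                    clinical_diagnosis=clinical_diagnosis,
                    pedigree_pattern=pedigree,
                    pattern=PlantPattern(pattern),
                    gene=genes[PlantPattern(pattern)],
                )
            )
    return tuple(plans)


def paper_counts_plan() -> tuple[PatientPlan, ...]:
    """The 168-patient preset cohort with planted diagnoses.

    86 definite diagnoses (60 AR, 18 AD, 8 XL — one of them an X-linked
    homozygous female, giving 147 causal alleles), 30 possible (single AR
    het) and 52 unsolved, arranged so that phenotype strata, causative-gene
    spectrum, pedigree reclassification (55 redefined; 37 solved simplex
    resolving 35 AR / 1 AD / 1 XL) and allele tallies reproduce the study
    cohort's printed structure end to end.
    """
    plans: list[PatientPlan] = []
    counter = 0

    def _new_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:03d}"

    def add(
        clinical: str,
        pattern: PlantPattern,
        gene: str | None,
        pedigree: PedigreePattern,
        sex: Sex | None = None,
    ) -> None:
        pid = _new_id()
        if sex is None:
            sex = Sex.MALE if counter % 2 else Sex.FEMALE
        plans.append(
            PatientPlan(
                patient_id=pid, sex=sex, clinical_diagnosis=clinical,
                pedigree_pattern=pedigree, pattern=pattern, gene=gene,
            )
        )

    # --- AR definite (60 compound heterozygotes; first 35 simplex) -------
    ar_definite: list[tuple[str, str]] = []  # (gene, clinical diagnosis)
    for gene, n in [
        ("USH2A", 13), ("EYS", 6), ("RP1", 4), ("ABCA4", 3), ("PDE6B", 3),
        ("CNGA1", 2), ("CRB1", 2), ("MERTK", 2), ("TULP1", 2), ("CERKL", 1),
        ("SPATA7", 1), ("CNGB1", 1), ("PDE6A", 1), ("RDH12", 1),
    ]:
        ar_definite += [(gene, "RP")] * n  # 42 retinitis pigmentosa
    ar_definite += [("CYP4V2", "RP")]  # presented as RP, refined to Bietti
    ar_definite += [("CNGB3", "CORD")]
    ar_definite += [("CNGB3", "STGD")]  # presented as STGD, refined to CORD
    ar_definite += [("MYO7A", "Usher"), ("USH1C", "Usher")]
    ar_definite += [("NMNAT1", "LCA"), ("RPE65", "LCA")]
    ar_definite += [("CEP290", "Joubert")]
    ar_definite += [("ABCA4", "STGD")] * 9
    ar_definite += [("RP1", "MD")]
    assert len(ar_definite) == 60
    for i, (gene, clinical) in enumerate(ar_definite):
        pedigree = PedigreePattern.SIMPLEX if i < 35 else PedigreePattern.AR
        add(clinical, PlantPattern.AR_COMPOUND_HET, gene, pedigree)

    # --- AD definite (18 single heterozygotes) ---------------------------
    ad_definite: list[tuple[str, str, PedigreePattern]] = [
        ("RHO", "RP", PedigreePattern.SIMPLEX),
        ("RHO", "RP", PedigreePattern.AR),
        ("RHO", "RP", PedigreePattern.AR),
        ("PRPF31", "RP", PedigreePattern.AR),
        ("PRPF31", "RP", PedigreePattern.AR),
        ("PRPH2", "RP", PedigreePattern.AR),
        ("PRPH2", "RP", PedigreePattern.AR),
        ("SNRNP200", "RP", PedigreePattern.AR),
        ("SNRNP200", "RP", PedigreePattern.AR),
        ("TOPORS", "RP", PedigreePattern.AR),
        ("TOPORS", "RP", PedigreePattern.AR),
        ("RP9", "RP", PedigreePattern.AR),
        ("CRX", "CORD", PedigreePattern.AR),
        ("CRX", "CORD", PedigreePattern.AR),
        ("BEST1", "VMD", PedigreePattern.AD),
        # dual-mode AD+AR genes need an AD pedigree for the AD rule to fire
        ("GUCY2D", "CORD", PedigreePattern.AD),
        ("GUCY2D", "CORD", PedigreePattern.AD),
        ("PROM1", "CORD", PedigreePattern.AD),
    ]
    for gene, clinical, pedigree in ad_definite:
        add(clinical, PlantPattern.AD_HET, gene, pedigree)

    # --- XL definite (7 hemizygous males + 1 homozygous female) ----------
    add("RP", PlantPattern.XL_HEMI, "RPGR", PedigreePattern.AR, Sex.MALE)
    add("RP", PlantPattern.XL_HEMI, "RPGR", PedigreePattern.AR, Sex.MALE)
    add("RP", PlantPattern.XL_HEMI, "RP2", PedigreePattern.AR, Sex.MALE)
    add("RP", PlantPattern.XL_HOM, "RP2", PedigreePattern.AR, Sex.FEMALE)
    add("CSNB", PlantPattern.XL_HEMI, "CACNA1F", PedigreePattern.AR, Sex.MALE)
    add("choroideraemia", PlantPattern.XL_HEMI, "CHM", PedigreePattern.XL, Sex.MALE)
    add("choroideraemia", PlantPattern.XL_HEMI, "CHM", PedigreePattern.XL, Sex.MALE)
    add("RP", PlantPattern.XL_HEMI, "CHM", PedigreePattern.SIMPLEX, Sex.MALE)

    # --- possible: single pathogenic AR het (30; first 10 simplex) -------
    possible: list[tuple[str, str]] = []
    for gene, n, clinical in [
        ("USH2A", 8, "RP"), ("EYS", 5, "RP"), ("ABCA4", 4, "RP"),
        ("PDE6B", 4, "RP"), ("ABCA4", 2, "CORD"), ("CNGB3", 1, "CORD"),
        ("MYO7A", 1, "Usher"), ("PROM1", 1, "MD"), ("IMPG2", 1, "MD"),
        ("IMPG2", 2, "VMD"), ("ABCA4", 1, "STGD"),
    ]:
        possible += [(gene, clinical)] * n
    assert len(possible) == 30
    for i, (gene, clinical) in enumerate(possible):
        pedigree = PedigreePattern.SIMPLEX if i < 10 else PedigreePattern.AR
        add(clinical, PlantPattern.AR_SINGLE_HET, gene, pedigree)

    # --- unsolved (52) ----------------------------------------------------
    unsolved: list[str] = (
        ["RP"] * 28 + ["CORD"] * 5 + ["CSNB"] + ["choroideraemia"]
        + ["VMD"] * 7 + ["MD"] * 8 + ["BBS"] + ["NCMD"]
    )
    assert len(unsolved) == 52
    pedigrees = (
        [PedigreePattern.SIMPLEX] * 13 + [PedigreePattern.AD] * 31
        + [PedigreePattern.XL] * 4 + [PedigreePattern.AR] * 4
    )
    for clinical, pedigree in zip(unsolved, pedigrees):
        add(clinical, PlantPattern.NONE, None, pedigree)

    assert len(plans) == 168
    return tuple(plans)


def paper_counts_config(rng_seed: int = 0) -> SimulationConfig:
    """Noise-free simulation preset over :func:`paper_counts_plan`.

    The allele plan fixes the 147 causal alleles of the 86 definite
    diagnoses at 89 missense, 26 nonsense, 13 frameshift insertions,
    12 frameshift deletions and 7 splicing, with 96 alleles previously
    reported and 51 novel (the single homozygote carries two copies of a
    reported missense variant).
    """
    return SimulationConfig(
        plans=paper_counts_plan(),
        rng_seed=rng_seed,
        causal_qc_fail_rate=0.0,
        second_allele_dropout=0.0,
        drop_known_rate=0.0,
        drop_acmg_rate=0.0,
        drop_consensus_rate=0.0,
        allele_plan=AllelePlan(
            consequence_counts={
                Consequence.MISSENSE: 87,
                Consequence.NONSENSE: 26,
                Consequence.FRAMESHIFT_INSERTION: 13,
                Consequence.FRAMESHIFT_DELETION: 12,
                Consequence.SPLICING: 7,
            },
            reported_count=94,
            hom_consequence=Consequence.MISSENSE,
            hom_reported=True,
        ),
    )
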