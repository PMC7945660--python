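"""Domain types and readers/writers for the IRD exome-triage pipeline.

The pipeline operates on four tabular inputs — per-patient variant calls
(VCF), a variant annotation table, a gene panel, and a patient/pedigree
table — and produces per-patient molecular-diagnosis records plus cohort
summaries.  This module defines the typed records that flow between stages
and the (deterministic, byte-stable) serialisation for each bespoke TSV.

Coordinates are 1-based and fully closed, as in VCF.  Indel alleles are
parsimony-trimmed (right then left) before being used as join keys so that
calls and annotations match regardless of caller dialect.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The six in-silico pathogenicity predictors consumed as verdict annotations.
#: PolyPhen-2 HDIV and HVar are distinct tools and contribute two votes.
PREDICTOR_TOOLS: tuple[str, ...] = (
    "sift",
    "pph2_hdiv",
    "pph2_hvar",
    "mutation_taster",
    "mutation_assessor",
    "fathmm",
)

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "hgvs_c", "hgvs_p",
    "known_disease_causing", "acmg_class", *PREDICTOR_TOOLS, "previously_reported",
]

DIAGNOSIS_COLUMNS = [
    "patient_id", "status", "gene", "variant_keys", "zygosities", "consequences",
    "previously_reported", "rationale_codes", "mode", "refined_inheritance",
    "refined_diagnosis",
]


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class AcmgClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


class Verdict(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


class Mode(str, enum.Enum):
    """Mendelian inheritance mode of a panel gene."""

    AD = "AD"
    AR = "AR"
    XL = "XL"


class PedigreePattern(str, enum.Enum):
    """Inheritance pattern inferred from the family pedigree alone."""

    AD = "AD"
    AR = "AR"
    XL = "XL"
    SIMPLEX = "simplex"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class DiagnosisStatus(str, enum.Enum):
    DEFINITE = "definite"
    POSSIBLE = "possible"
    NONE = "none"


class VariantKey(NamedTuple):
    """Normalised (chrom, pos, ref, alt) identity of a variant."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # chrom:pos:ref:alt, used in TSV output
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Parsimony-trim an allele pair to its left-aligned minimal representation.

    Shared trailing bases are removed first, then shared leading bases
    (advancing ``pos``), always retaining at least one base on each allele.
    SNVs pass through unchanged.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One called variant allele in one patient, with depth evidence."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Zygosity
    total_depth: int
    alt_depth: int
    vaf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} > total_depth {self.total_depth}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")

    @property
    def key(self) -> VariantKey:
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Gene/consequence/pathogenicity-evidence annotations for one variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    hgvs_c: str
    hgvs_p: str
    known_disease_causing: bool
    acmg_class: AcmgClass
    predictor_verdicts: Mapping[str, Verdict]
    previously_reported: bool

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if set(self.predictor_verdicts) != set(PREDICTOR_TOOLS):
            raise ValueError(
                f"expected verdicts for exactly the {len(PREDICTOR_TOOLS)} tools "
                f"{PREDICTOR_TOOLS}, got {sorted(self.predictor_verdicts)}"
            )

    @property
    def key(self) -> VariantKey:
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PanelGene:
    """A disease-gene panel entry with inheritance mode(s) and phenotype group(s)."""

    symbol: str
    modes: frozenset[Mode]
    phenotype_groups: frozenset[str]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError(f"panel gene {self.symbol} has no inheritance mode")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: Sex
    clinical_diagnosis: str
    pedigree_pattern: PedigreePattern


@dataclass(frozen=True)
class CausalVariant:
    """A causal-variant snapshot carried inside a MolecularDiagnosis.

    Zygosity, consequence, novelty and the satisfied pathogenicity criteria
    are copied in at diagnosis time so the diagnosis record is self-contained
    (cohort summaries can be recomputed from the written diagnoses table).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Zygosity
    consequence: Consequence
    previously_reported: bool
    rationale: frozenset[str]

    @property
    def key(self) -> VariantKey:
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_alleles(self) -> int:
        """Mutant-allele copies contributed: homozygotes count two."""
        return 2 if self.zygosity is Zygosity.HOM else 1


@dataclass(frozen=True)
class MolecularDiagnosis:
    """Per-patient outcome of the diagnosis engine."""

    patient_id: str
    status: DiagnosisStatus
    gene: str | None
    causal_variants: tuple[CausalVariant, ...]
    mode: Mode | None
    refined_inheritance: Mode | None
    refined_diagnosis: str | None

    def __post_init__(self) -> None:
        if self.status is DiagnosisStatus.DEFINITE:
            if not (self.gene and self.mode and self.causal_variants):
                raise ValueError(
                    f"{self.patient_id}: definite diagnosis requires gene, mode "
                    "and at least one causal variant"
                )
            if self.mode is Mode.AR:
                n = sum(v.n_alleles for v in self.causal_variants)
                if n != 2:
                    raise ValueError(
                        f"{self.patient_id}: AR definite diagnosis must carry two "
                        f"mutant alleles, got {n}"
                    )
        elif self.status is DiagnosisStatus.POSSIBLE:
            if self.mode is not Mode.AR or len(self.causal_variants) != 1 \
                    or self.causal_variants[0].zygosity is not Zygosity.HET:
                raise ValueError(
                    f"{self.patient_id}: possible diagnosis means exactly one "
                    "heterozygous variant in an AR gene"
                )
        else:
            if self.gene is not None or self.causal_variants:
                raise ValueError(
                    f"{self.patient_id}: status 'none' must not carry a gene"
                )


@dataclass
class Cohort:
    """All inputs for one pipeline run, cross-validated."""

    patients: list[Patient]
    calls: list[VariantCall]
    annotations: dict[VariantKey, VariantAnnotation]
    panel: list[PanelGene]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient_id in cohort")
        known = set(ids)
        for c in self.calls:
            if c.patient_id not in known:
                raise ValueError(f"call for unknown patient {c.patient_id}")

    @property
    def panel_map(self) -> dict[str, PanelGene]:
        return {g.symbol.upper(): g for g in self.panel}

    def calls_by_patient(self) -> dict[str, list[VariantCall]]:
        out: dict[str, list[VariantCall]] = {p.patient_id: [] for p in self.patients}
        for c in self.calls:
            out[c.patient_id].append(c)
        return out


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

X_CHROMS = {"X", "chrX"}


def read_vcf(
    path: str | Path,
    patient_id: str,
    infer_hemizygous_x: bool = True,
) -> list[VariantCall]:
    """Read one patient's VCF into VariantCall records.

    Multi-allelic records are decomposed into one call per ALT allele.
    Zygosity is derived from GT: diploid with both alleles alternate -> hom,
    one alternate -> het; haploid alternate -> hemi.  When
    ``infer_hemizygous_x`` is set (default), heterozygous male calls on the X
    chromosome are reported as hemizygous.  Records lacking GT, DP or AD are
    skipped with a warning.

    Sex is not encoded in VCF, so the male-X inference applies to every het X
    call in this file; callers that know the patient is female should pass
    ``infer_hemizygous_x=False``.
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    calls: list[VariantCall] = []
    skipped = 0
    for record in vcf:
        genotypes = record.genotypes
        dp = record.format("DP")
        ad = record.format("AD")
        if not genotypes or dp is None or ad is None:
            skipped += 1
            logger.warning(
                "%s: record %s:%s missing GT/DP/AD, skipped",
                path.name, record.CHROM, record.POS,
            )
            continue
        alleles = [a for a in genotypes[0][:-1] if a >= 0]
        total_depth = int(dp[0][0])
        ad_row = ad[0]
        ploidy = len(alleles)
        for alt_index, alt in enumerate(record.ALT, start=1):
            if alt_index not in alleles:
                continue
            copies = alleles.count(alt_index)
            if ploidy == 1:
                zyg = Zygosity.HEMI
            elif copies == ploidy:
                zyg = Zygosity.HOM
            else:
                zyg = Zygosity.HET
            if (
                zyg is Zygosity.HET
                and infer_hemizygous_x
                and record.CHROM in X_CHROMS
            ):
                zyg = Zygosity.HEMI
            alt_depth = int(ad_row[alt_index]) if alt_index < len(ad_row) else 0
            vaf = alt_depth / total_depth if total_depth > 0 else 0.0
            calls.append(
                VariantCall(
                    patient_id=patient_id,
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    zygosity=zyg,
                    total_depth=total_depth,
                    alt_depth=min(alt_depth, total_depth),
                    vaf=min(vaf, 1.0),
                )
            )
    if skipped:
        logger.warning("%s: skipped %d records lacking GT/DP/AD", path.name, skipped)
    return calls


# ---------------------------------------------------------------------------
# Predictor verdict vocabulary
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", ".", "na", "nan", "none", "missing", "unknown", "-"}


def _data_path(name: str) -> Path:
    from importlib import resources

    return Path(str(resources.files("ird_triage").joinpath("data", name)))


def load_verdict_map(path: str | Path | None = None) -> dict[str, dict[str, str]]:
    """Load the per-tool raw-label -> {damaging, tolerated} mapping (YAML)."""
    path = Path(path) if path else _data_path("predictor_labels.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {tool: {str(k).lower(): v for k, v in m.items()} for tool, m in raw.items()}


def _parse_verdict(tool: str, raw: object, verdict_map: Mapping[str, Mapping[str, str]]) -> Verdict:
    token = str(raw).strip().lower().replace(" ", "_")
    if token in _MISSING_TOKENS:
        return Verdict.MISSING
    if token in (Verdict.DAMAGING.value, Verdict.TOLERATED.value):
        return Verdict(token)
    mapped = verdict_map.get(tool, {}).get(token)
    if mapped is None:
        logger.warning("unknown %s label %r treated as missing", tool, raw)
        return Verdict.MISSING
    return Verdict(mapped)


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path,
    verdict_map: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[VariantKey, VariantAnnotation]:
    """Read the variant annotation table keyed by normalised variant key."""
    if verdict_map is None:
        verdict_map = load_verdict_map()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        logger.warning("%s: empty annotation table", path)
        return {}
    out: dict[VariantKey, VariantAnnotation] = {}
    for row in df.itertuples(index=False):
        raw_cons = str(row.consequence).strip().lower()
        try:
            consequence = Consequence(raw_cons)
        except ValueError:
            logger.warning("unknown consequence %r mapped to 'other'", row.consequence)
            consequence = Consequence.OTHER
        verdicts = {
            tool: _parse_verdict(tool, getattr(row, tool, "missing"), verdict_map)
            for tool in PREDICTOR_TOOLS
        }
        ann = VariantAnnotation(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            gene=str(row.gene),
            consequence=consequence,
            hgvs_c=str(row.hgvs_c),
            hgvs_p=str(row.hgvs_p),
            known_disease_causing=str(row.known_disease_causing) in ("1", "True", "true"),
            acmg_class=AcmgClass(str(row.acmg_class).strip().lower()),
            predictor_verdicts=verdicts,
            previously_reported=str(row.previously_reported) in ("1", "True", "true"),
        )
        out[ann.key] = ann
    return out


def read_panel(path: str | Path) -> list[PanelGene]:
    """Read the gene panel TSV (symbol, ';'-joined modes, ';'-joined groups)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        logger.warning("%s: empty panel file", path)
        return []
    genes: list[PanelGene] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        symbol = str(row.symbol).strip().upper()
        if symbol in seen:
            raise ValueError(f"duplicate panel symbol {symbol}")
        seen.add(symbol)
        try:
            modes = frozenset(Mode(m.strip()) for m in str(row.modes).split(";") if m.strip())
        except ValueError as exc:
            raise ValueError(f"unknown inheritance mode for {symbol}: {row.modes}") from exc
        groups = frozenset(
            g.strip() for g in str(row.phenotype_groups).split(";") if g.strip()
        )
        genes.append(PanelGene(symbol=symbol, modes=modes, phenotype_groups=groups))
    return genes


def read_patients(path: str | Path) -> list[Patient]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        logger.warning("%s: empty patient table", path)
        return []
    return [
        Patient(
            patient_id=str(row.patient_id),
            sex=Sex(str(row.sex).strip().lower()),
            clinical_diagnosis=str(row.clinical_diagnosis).strip(),
            pedigree_pattern=PedigreePattern(str(row.pedigree_pattern).strip()),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Writers (deterministic: fixed column order, sorted by patient_id)
# ---------------------------------------------------------------------------

def write_panel(panel: Sequence[PanelGene], path: str | Path) -> None:
    rows = [
        {
            "symbol": g.symbol,
            "modes": ";".join(sorted(m.value for m in g.modes)),
            "phenotype_groups": ";".join(sorted(g.phenotype_groups)),
        }
        for g in sorted(panel, key=lambda g: g.symbol)
    ]
    pd.DataFrame(rows, columns=["symbol", "modes", "phenotype_groups"]).to_csv(
        path, sep="\t", index=False
    )


def write_patients(patients: Sequence[Patient], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "sex": p.sex.value,
            "clinical_diagnosis": p.clinical_diagnosis,
            "pedigree_pattern": p.pedigree_pattern.value,
        }
        for p in sorted(patients, key=lambda p: p.patient_id)
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "sex", "clinical_diagnosis", "pedigree_pattern"]
    ).to_csv(path, sep="\t", index=False)


def write_annotations(
    annotations: Mapping[VariantKey, VariantAnnotation], path: str | Path
) -> None:
    rows = []
    for key in sorted(annotations):
        a = annotations[key]
        row = {
            "chrom": a.chrom,
            "pos": a.pos,
            "ref": a.ref,
            "alt": a.alt,
            "gene": a.gene,
            "consequence": a.consequence.value,
            "hgvs_c": a.hgvs_c,
            "hgvs_p": a.hgvs_p,
            "known_disease_causing": int(a.known_disease_causing),
            "acmg_class": a.acmg_class.value,
            "previously_reported": int(a.previously_reported),
        }
        for tool in PREDICTOR_TOOLS:
            row[tool] = a.predictor_verdicts[tool].value
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_diagnoses(diagnoses: Sequence[MolecularDiagnosis], path: str | Path) -> None:
    """Write the per-patient diagnosis table, sorted by patient_id."""
    rows = []
    for d in sorted(diagnoses, key=lambda d: d.patient_id):
        rows.append(
            {
                "patient_id": d.patient_id,
                "status": d.status.value,
                "gene": d.gene or "",
                "variant_keys": ";".join(str(v.key) for v in d.causal_variants),
                "zygosities": ";".join(v.zygosity.value for v in d.causal_variants),
                "consequences": ";".join(v.consequence.value for v in d.causal_variants),
                "previously_reported": ";".join(
                    str(int(v.previously_reported)) for v in d.causal_variants
                ),
                "rationale_codes": ";".join(
                    "|".join(sorted(v.rationale)) for v in d.causal_variants
                ),
                "mode": d.mode.value if d.mode else "",
                "refined_inheritance": d.refined_inheritance.value
                if d.refined_inheritance
                else "",
                "refined_diagnosis": d.refined_diagnosis or "",
            }
        )
    pd.DataFrame(rows, columns=DIAGNOSIS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_diagnoses(path: str | Path) -> list[MolecularDiagnosis]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[MolecularDiagnosis] = []
    for row in df.itertuples(index=False):
        causal: list[CausalVariant] = []
        if row.variant_keys:
            keys = row.variant_keys.split(";")
            zygs = row.zygosities.split(";")
            cons = row.consequences.split(";")
            reps = row.previously_reported.split(";")
            rats = row.rationale_codes.split(";")
            for k, z, c, r, ra in zip(keys, zygs, cons, reps, rats):
                vk = VariantKey.parse(k)
                causal.append(
                    CausalVariant(
                        chrom=vk.chrom,
                        pos=vk.pos,
                        ref=vk.ref,
                        alt=vk.alt,
                        zygosity=Zygosity(z),
                        consequence=Consequence(c),
                        previously_reported=r == "1",
                        rationale=frozenset(ra.split("|")) if ra else frozenset(),
                    )
                )
        out.append(
            MolecularDiagnosis(
                patient_id=row.patient_id,
                status=DiagnosisStatus(row.status),
                gene=row.gene or None,
                causal_variants=tuple(causal),
                mode=Mode(row.mode) if row.mode else None,
                refined_inheritance=Mode(row.refined_inheritance)
                if row.refined_inheritance
                else None,
                refined_diagnosis=row.refined_diagnosis or None,
            )
        )
    return out


def write_summary(summary_dict: Mapping, path: str | Path) -> None:
    """Write a machine-readable summary as deterministic (sorted-key) JSON."""
    import json

    with open(path, "w") as fh:
        json.dump(summary_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
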