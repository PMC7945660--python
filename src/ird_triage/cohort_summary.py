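"""Cohort-level summarisation: detection rates, gene rankings, allele tallies.

Percentages are reported to one decimal place using round-half-up, the
convention used in clinical-yield reporting (86/168 prints as 51.2%).
Phenotype denominators use the post-refinement clinical diagnosis by
default: a patient whose presenting RP was genetically redefined as
choroideraemia counts in the choroideraemia stratum.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

from .diagnosis_engine import Reclassification, reclassify_cohort
from .io_model import (
    Consequence,
    DiagnosisStatus,
    MolecularDiagnosis,
    Mode,
    Patient,
)


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StratumRate:
    solved: int
    total: int

    @property
    def rate_pct(self) -> float:
        return pct(self.solved, self.total)


@dataclass(frozen=True)
class GeneRank:
    gene: str
    n_patients: int
    share_pct: float


@dataclass(frozen=True)
class AlleleTally:
    """Mutant-allele bookkeeping over causal variants of definite diagnoses.

    Heterozygous and hemizygous causal variants contribute one allele each;
    homozygous variants contribute two.
    """

    total: int
    previously_reported: int
    novel: int
    by_consequence: dict[str, int]

    @property
    def novel_fraction_pct(self) -> float:
        return pct(self.novel, self.total)

    def consequence_fraction_pct(self, consequence: Consequence | str) -> float:
        key = consequence.value if isinstance(consequence, Consequence) else consequence
        return pct(self.by_consequence.get(key, 0), self.total)


@dataclass
class CohortSummary:
    overall: StratumRate
    per_phenotype: dict[str, StratumRate]
    possible_count: int
    n_genes: int
    gene_ranking_overall: list[GeneRank]
    gene_ranking_by_phenotype: dict[str, list[GeneRank]]
    gene_ranking_by_mode: dict[str, list[GeneRank]]
    alleles: AlleleTally
    reclassification: Reclassification

    @property
    def possible_rate_pct(self) -> float:
        return pct(self.possible_count, self.overall.total)

    @property
    def combined_rate_pct(self) -> float:
        """Definite-or-possible yield as a percentage of the whole cohort."""
        return pct(self.overall.solved + self.possible_count, self.overall.total)

    def to_dict(self) -> dict:
        def ranks(rs: list[GeneRank]) -> list[dict]:
            return [
                {"gene": r.gene, "n_patients": r.n_patients, "share_pct": r.share_pct}
                for r in rs
            ]

        return {
            "overall": {
                "solved": self.overall.solved,
                "total": self.overall.total,
                "rate_pct": self.overall.rate_pct,
            },
            "per_phenotype": {
                label: {"solved": s.solved, "total": s.total, "rate_pct": s.rate_pct}
                for label, s in sorted(self.per_phenotype.items())
            },
            "possible_count": self.possible_count,
            "possible_rate_pct": self.possible_rate_pct,
            "combined_rate_pct": self.combined_rate_pct,
            "n_genes": self.n_genes,
            "gene_ranking_overall": ranks(self.gene_ranking_overall),
            "gene_ranking_by_phenotype": {
                k: ranks(v) for k, v in sorted(self.gene_ranking_by_phenotype.items())
            },
            "gene_ranking_by_mode": {
                k: ranks(v) for k, v in sorted(self.gene_ranking_by_mode.items())
            },
            "alleles": {
                "total": self.alleles.total,
                "previously_reported": self.alleles.previously_reported,
                "novel": self.alleles.novel,
                "novel_fraction_pct": self.alleles.novel_fraction_pct,
                "by_consequence": dict(sorted(self.alleles.by_consequence.items())),
            },
            "reclassification": self.reclassification.to_dict(),
        }


def count_mutant_alleles(diagnoses: Sequence[MolecularDiagnosis]) -> AlleleTally:
    """Tally causal mutant alleles across definite diagnoses.

    Variants are de-duplicated per patient (a compound-het pair is two
    distinct variants); a homozygous variant counts two allele copies.
    """
    total = reported = 0
    by_consequence: Counter[str] = Counter()
    for d in diagnoses:
        if d.status is not DiagnosisStatus.DEFINITE:
            continue
        seen = set()
        for v in d.causal_variants:
            if v.key in seen:
                continue
            seen.add(v.key)
            total += v.n_alleles
            if v.previously_reported:
                reported += v.n_alleles
            by_consequence[v.consequence.value] += v.n_alleles
    return AlleleTally(
        total=total,
        previously_reported=reported,
        novel=total - reported,
        by_consequence=dict(by_consequence),
    )


def _patient_stratum(
    d: MolecularDiagnosis,
    patient: Patient,
    denominator: Literal["refined", "clinical"],
) -> str:
    if denominator == "refined" and d.status is DiagnosisStatus.DEFINITE:
        return d.refined_diagnosis or patient.clinical_diagnosis
    return patient.clinical_diagnosis


def _strata(
    diagnoses: Sequence[MolecularDiagnosis],
    patients: Sequence[Patient],
    denominator: Literal["refined", "clinical"],
) -> dict[str, str]:
    by_id = {p.patient_id: p for p in patients}
    return {
        d.patient_id: _patient_stratum(d, by_id[d.patient_id], denominator)
        for d in diagnoses
    }


def _rank(counter: Counter[str], denominator: int) -> list[GeneRank]:
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return [GeneRank(g, n, pct(n, denominator)) for g, n in ordered]


def rank_genes(
    diagnoses: Sequence[MolecularDiagnosis],
    patients: Sequence[Patient],
    stratum: str = "all",
    denominator: Literal["refined", "clinical"] = "refined",
) -> list[GeneRank]:
    """Rank causative genes by number of definitely diagnosed patients.

    ``stratum`` selects all solved patients ("all"), a phenotype label, or an
    inheritance mode ("AD"/"AR"/"XL").  Share denominators are solved
    patients within the stratum; ties sort alphabetically.
    """
    mode_labels = {m.value for m in Mode}
    pheno_labels = {p.clinical_diagnosis for p in patients} | {
        d.refined_diagnosis for d in diagnoses if d.refined_diagnosis
    }
    if stratum != "all" and stratum not in mode_labels | pheno_labels:
        raise ValueError(f"unknown stratum {stratum!r}")
    strata = _strata(diagnoses, patients, denominator)
    counter: Counter[str] = Counter()
    solved = 0
    for d in diagnoses:
        if d.status is not DiagnosisStatus.DEFINITE:
            continue
        if stratum == "all":
            selected = True
        elif stratum in mode_labels:
            selected = d.refined_inheritance is not None and (
                d.refined_inheritance.value == stratum
            )
        else:
            selected = strata[d.patient_id] == stratum
        if selected:
            solved += 1
            counter[d.gene] += 1
    return _rank(counter, solved)


def summarize(
    diagnoses: Sequence[MolecularDiagnosis],
    patients: Sequence[Patient],
    denominator: Literal["refined", "clinical"] = "refined",
) -> CohortSummary:
    """Compute the full cohort summary from per-patient diagnoses.

    Requires exactly one diagnosis record per patient; the result is
    invariant to patient order.
    """
    ids = [d.patient_id for d in diagnoses]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient diagnosis")
    patient_ids = {p.patient_id for p in patients}
    if set(ids) != patient_ids:
        raise ValueError("diagnoses must cover every patient exactly once")

    strata = _strata(diagnoses, patients, denominator)
    solved_by_stratum: Counter[str] = Counter()
    total_by_stratum: Counter[str] = Counter()
    possible_count = 0
    n_solved = 0
    genes_overall: Counter[str] = Counter()
    genes_by_pheno: dict[str, Counter[str]] = {}
    genes_by_mode: dict[str, Counter[str]] = {}
    for d in sorted(diagnoses, key=lambda d: d.patient_id):
        label = strata[d.patient_id]
        total_by_stratum[label] += 1
        if d.status is DiagnosisStatus.DEFINITE:
            n_solved += 1
            solved_by_stratum[label] += 1
            genes_overall[d.gene] += 1
            genes_by_pheno.setdefault(label, Counter())[d.gene] += 1
            genes_by_mode.setdefault(d.refined_inheritance.value, Counter())[
                d.gene
            ] += 1
        elif d.status is DiagnosisStatus.POSSIBLE:
            possible_count += 1

    n_total = len(patients)
    per_phenotype = {
        label: StratumRate(solved_by_stratum.get(label, 0), total)
        for label, total in total_by_stratum.items()
    }
    return CohortSummary(
        overall=StratumRate(n_solved, n_total),
        per_phenotype=per_phenotype,
        possible_count=possible_count,
        n_genes=len(genes_overall),
        gene_ranking_overall=_rank(genes_overall, n_solved),
        gene_ranking_by_phenotype={
            label: _rank(c, solved_by_stratum[label])
            for label, c in genes_by_pheno.items()
        },
        gene_ranking_by_mode={
            label: _rank(c, sum(c.values())) for label, c in genes_by_mode.items()
        },
        alleles=count_mutant_alleles(diagnoses),
        reclassification=reclassify_cohort(diagnoses, patients),
    )


def _md_table(headers: list[str], rows: list[list]) -> str:
    lines = [
        "| " + " | ".join(headers) + " |",
        "| " + " | ".join("---" for _ in headers) + " |",
    ]
    for row in rows:
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def render_markdown(summary: CohortSummary) -> str:
    """Human-readable markdown rendering of the cohort summary."""
    parts = ["# Cohort summary", ""]
    parts.append(
        f"Definite molecular diagnosis: {summary.overall.solved}/"
        f"{summary.overall.total} ({summary.overall.rate_pct}%); possible: "
        f"{summary.possible_count} ({summary.possible_rate_pct}%); combined "
        f"definite+possible: {summary.combined_rate_pct}%."
    )
    parts += ["", "## Detection rate by phenotype", ""]
    parts.append(
        _md_table(
            ["Phenotype", "Solved", "Total", "Rate (%)"],
            [
                [label, s.solved, s.total, s.rate_pct]
                for label, s in sorted(summary.per_phenotype.items())
            ],
        )
    )
    parts += ["", "## Causative genes (all solved patients)", ""]
    parts.append(
        _md_table(
            ["Gene", "Patients", "Share (%)"],
            [[r.gene, r.n_patients, r.share_pct] for r in summary.gene_ranking_overall],
        )
    )
    a = summary.alleles
    parts += ["", "## Mutant alleles", ""]
    parts.append(
        f"{a.total} mutant alleles in {summary.n_genes} genes; "
        f"{a.previously_reported} previously reported, {a.novel} novel "
        f"({a.novel_fraction_pct}%)."
    )
    parts.append("")
    parts.append(
        _md_table(
            ["Consequence", "Alleles", "Share (%)"],
            [
                [c, n, pct(n, a.total)]
                for c, n in sorted(a.by_consequence.items(), key=lambda kv: -kv[1])
            ],
        )
    )
    r = summary.reclassification
    parts += ["", "## Inheritance reclassification (definite diagnoses)", ""]
    parts.append(
        f"{r.n_inheritance_redefined}/{summary.overall.total} patients "
        f"({pct(r.n_inheritance_redefined, summary.overall.total)}%) had their "
        f"inheritance pattern redefined; {r.n_simplex} simplex cases resolved as "
        + ", ".join(f"{m}: {n}" for m, n in r.simplex_by_mode.items())
        + "."
    )
    parts.append("")
    ct = r.crosstab
    parts.append(
        _md_table(
            ["Pedigree \\ Refined"] + list(ct.columns),
            [[idx] + [int(v) for v in ct.loc[idx]] for idx in ct.index],
        )
    )
    parts.append("")
    return "\n".join(parts)
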