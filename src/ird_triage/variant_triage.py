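"""Variant-level triage: QC filtering, panel restriction, pathogenicity rules.

A variant is classified pathogenic when at least one of four criteria holds:

1. ``KNOWN``      — previously described as disease causing (HGMD/literature);
2. ``ACMG``       — classified pathogenic or likely pathogenic under ACMG/AMP;
3. ``CONSENSUS``  — called damaging by a strict majority of the six in-silico
   predictors (SIFT, PolyPhen-2 HDIV, PolyPhen-2 HVar, MutationTaster,
   MutationAssessor, FATHMM);
4. ``TRUNCATING`` — protein-truncating consequence (nonsense or frameshift).

All satisfied criteria are recorded, not just the first.  Splice variants are
not treated as truncating; they can qualify only through criteria 1-3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from .io_model import (
    AcmgClass,
    Consequence,
    PanelGene,
    PREDICTOR_TOOLS,
    VariantAnnotation,
    VariantCall,
    VariantKey,
    Verdict,
)

logger = logging.getLogger(__name__)

#: Rationale codes, ordered by reporting strength.
RATIONALE_CODES = ("KNOWN", "ACMG", "CONSENSUS", "TRUNCATING")

TRUNCATING_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.FRAMESHIFT_DELETION,
    }
)

PATHOGENIC_ACMG = frozenset({AcmgClass.PATHOGENIC, AcmgClass.LIKELY_PATHOGENIC})


@dataclass(frozen=True)
class QcThresholds:
    """Retention thresholds for call-level quality control.

    Removal conditions are strict inequalities (depth < min_depth,
    VAF < min_vaf, alt reads < min_alt_reads), so a call sitting exactly on
    a threshold is kept.
    """

    min_depth: int = 10
    min_vaf: float = 0.10
    min_alt_reads: int = 2

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_vaf <= 0 or self.min_alt_reads <= 0:
            raise ValueError("QC thresholds must be strictly positive")


@dataclass(frozen=True)
class PathogenicityCall:
    """Outcome of the four-criterion rule engine for one variant."""

    key: VariantKey
    pathogenic: bool
    rationale: frozenset[str]

    def __post_init__(self) -> None:
        if self.pathogenic != bool(self.rationale):
            raise ValueError("pathogenic must hold iff rationale is non-empty")


def apply_qc_filter(
    calls: Sequence[VariantCall], thresholds: QcThresholds | None = None
) -> list[VariantCall]:
    """Drop low-quality calls; preserves input order, logs removals per reason."""
    thresholds = thresholds or QcThresholds()
    kept: list[VariantCall] = []
    removed = {"depth": 0, "vaf": 0, "alt_reads": 0}
    for c in calls:
        low_depth = c.total_depth < thresholds.min_depth
        low_vaf = c.vaf < thresholds.min_vaf
        low_alt = c.alt_depth < thresholds.min_alt_reads
        if low_depth or low_vaf or low_alt:
            if low_depth:
                removed["depth"] += 1
            if low_vaf:
                removed["vaf"] += 1
            if low_alt:
                removed["alt_reads"] += 1
            continue
        kept.append(c)
    n_removed = len(calls) - len(kept)
    if n_removed:
        logger.info(
            "QC removed %d/%d calls (depth<%d: %d, vaf<%.2f: %d, alt<%d: %d)",
            n_removed, len(calls), thresholds.min_depth, removed["depth"],
            thresholds.min_vaf, removed["vaf"], thresholds.min_alt_reads,
            removed["alt_reads"],
        )
    return kept


def restrict_to_panel(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    panel: Sequence[PanelGene] | Mapping[str, PanelGene],
) -> list[tuple[VariantCall, VariantAnnotation]]:
    """Keep calls whose annotated gene is on the panel (case-insensitive).

    Calls with no resolvable annotation are dropped and counted.
    """
    if isinstance(panel, Mapping):
        symbols = {s.upper() for s in panel}
    else:
        symbols = {g.symbol.upper() for g in panel}
    out: list[tuple[VariantCall, VariantAnnotation]] = []
    unannotated = 0
    for c in calls:
        ann = annotations.get(c.key)
        if ann is None:
            unannotated += 1
            continue
        if ann.gene.upper() in symbols:
            out.append((c, ann))
    if unannotated:
        logger.info("dropped %d calls without annotation", unannotated)
    return out


def predictor_consensus(
    verdicts: Mapping[str, Verdict],
    denominator: Literal["fixed6", "available"] = "fixed6",
) -> bool:
    """True when a strict majority of the six predictors calls the variant damaging.

    The denominator is fixed at six — a missing prediction counts as
    not-damaging — so the rule is ``damaging >= 4``.  With
    ``denominator="available"`` the majority is taken over non-missing
    verdicts instead (sensitivity analysis; all-missing returns False).
    """
    if len(verdicts) != len(PREDICTOR_TOOLS):
        raise ValueError(
            f"expected exactly {len(PREDICTOR_TOOLS)} verdicts, got {len(verdicts)}"
        )
    n_damaging = sum(1 for v in verdicts.values() if v is Verdict.DAMAGING)
    if denominator == "fixed6":
        return n_damaging * 2 > len(PREDICTOR_TOOLS)
    if denominator == "available":
        n_avail = sum(1 for v in verdicts.values() if v is not Verdict.MISSING)
        return n_avail > 0 and n_damaging * 2 > n_avail
    raise ValueError(f"unknown denominator rule {denominator!r}")


def is_truncating(consequence: Consequence) -> bool:
    """Protein-truncating under the classification rule: nonsense or frameshift."""
    return consequence in TRUNCATING_CONSEQUENCES


def classify_pathogenicity(
    annotation: VariantAnnotation,
    consensus_denominator: Literal["fixed6", "available"] = "fixed6",
) -> PathogenicityCall:
    """Evaluate the four pathogenicity criteria; record every satisfied one."""
    rationale = set()
    if annotation.known_disease_causing:
        rationale.add("KNOWN")
    if annotation.acmg_class in PATHOGENIC_ACMG:
        rationale.add("ACMG")
    if predictor_consensus(annotation.predictor_verdicts, consensus_denominator):
        rationale.add("CONSENSUS")
    if is_truncating(annotation.consequence):
        rationale.add("TRUNCATING")
    return PathogenicityCall(
        key=annotation.key,
        pathogenic=bool(rationale),
        rationale=frozenset(rationale),
    )


def flag_for_validation(
    pathogenic_calls: Sequence[VariantCall], min_coverage: int = 20
) -> list[VariantKey]:
    """Keys of pathogenic calls needing orthogonal (Sanger) confirmation.

    Flags exactly the calls with read depth strictly below ``min_coverage``.
    """
    flagged = [c.key for c in pathogenic_calls if c.total_depth < min_coverage]
    if pathogenic_calls:
        logger.info(
            "validation flagging: %d/%d pathogenic calls below %dx (%.1f%%)",
            len(flagged), len(pathogenic_calls), min_coverage,
            100.0 * len(flagged) / len(pathogenic_calls),
        )
    return flagged
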