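import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from ird_triage.io_model import (
    AcmgClass,
    Consequence,
    PREDICTOR_TOOLS,
    VariantAnnotation,
    VariantCall,
    Verdict,
    Zygosity,
)


def make_call(
    patient_id="P1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    zygosity=Zygosity.HET,
    total_depth=40,
    alt_depth=20,
    vaf=None,
):
    return VariantCall(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        zygosity=zygosity,
        total_depth=total_depth,
        alt_depth=alt_depth,
        vaf=alt_depth / total_depth if vaf is None else vaf,
    )


def make_annotation(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    gene="USH2A",
    consequence=Consequence.MISSENSE,
    known=False,
    acmg=AcmgClass.UNCERTAIN,
    n_damaging=0,
    n_missing=0,
    previously_reported=False,
):
    verdicts = {}
    for i, tool in enumerate(PREDICTOR_TOOLS):
        if i < n_damaging:
            verdicts[tool] = Verdict.DAMAGING
        elif i < n_damaging + n_missing:
            verdicts[tool] = Verdict.MISSING
        else:
            verdicts[tool] = Verdict.TOLERATED
    return VariantAnnotation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        hgvs_c="c.100A>G",
        hgvs_p="p.(Arg34Gly)",
        known_disease_causing=known,
        acmg_class=acmg,
        predictor_verdicts=verdicts,
        previously_reported=previously_reported,
    )


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture
def annotation_factory():
    return make_annotation
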