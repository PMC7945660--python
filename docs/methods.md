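# Methods

This note records the procedures the package implements, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the places where the design was genuinely open.

## Variant quality control

Calls are removed when read depth < 10, variant allele fraction (VAF) < 10 %
or alternate-read count < 2. The removal conditions are strict
inequalities, so retention uses `>=` at every threshold: a call at exactly
10× depth, exactly 10 % VAF and exactly 2 alternate reads is kept. The
thresholds live in `QcThresholds` (units: reads, fraction, reads) and in the
pipeline YAML config (`min_depth`, `min_vaf`, `min_alt_reads`). The filter
is idempotent, order-preserving, and commutes with panel restriction.

VCF parsing decomposes multi-allelic records into one call per ALT allele,
with per-allele depth taken from AD. Join keys are parsimony-trimmed
(shared suffix first, then shared prefix, keeping one base) so indel
representation differences between callers do not break the
call-to-annotation join. True left-alignment against a reference genome is
out of scope; the trimming is representation-stable for padding dialects
only.

Hemizygosity is taken from haploid GT, and additionally inferred for
heterozygous male calls on chrX when `infer_hemizygous_x` is on (default).
Sex is not encoded in VCF, so the pipeline applies the inference per
patient using the patient table.

## Pathogenicity rule engine

Four criteria, OR-combined, all satisfied criteria recorded:

| code | criterion |
| --- | --- |
| KNOWN | previously described as disease-causing (HGMD/literature flag) |
| ACMG | pathogenic or likely pathogenic under ACMG/AMP (consumed as an input class; evidence codes are not recomputed) |
| CONSENSUS | damaging verdicts from a strict majority of the six predictors |
| TRUNCATING | nonsense or frameshift (insertion or deletion) consequence |

Consensus details. The predictor panel is fixed: SIFT, PolyPhen-2 HDIV,
PolyPhen-2 HVar (two independent votes), MutationTaster, MutationAssessor,
FATHMM. "More than half of six" means ≥ 4 damaging; the denominator stays
6 when verdicts are missing (missing = not damaging). An available-tools
denominator is provided behind `consensus_denominator: available` for
sensitivity analysis. Raw tool labels are mapped to
damaging/tolerated/missing by a shipped, editable YAML
(`data/predictor_labels.yaml`); PolyPhen-2 `possibly_damaging` maps to
tolerated by default, since the rule names the "likely damaging" category.
The consensus rule is applied wherever verdicts exist, not only to missense
variants — whether it should be missense-only is ambiguous, and restricting
it would only remove CONSENSUS votes from variants that typically qualify
as TRUNCATING anyway.

Splice variants are **not** truncating under this rule; they can qualify
only via KNOWN/ACMG/CONSENSUS. The engine evaluates the single supplied
consequence per variant; transcript arbitration happens upstream.

The engine is monotone: strengthening any single input (adding a damaging
verdict, upgrading the ACMG class, setting the known flag, switching the
consequence to nonsense) never flips pathogenic to non-pathogenic. The test
suite checks the full 2 × 5 × 7 × 7 input grid against an independently
coded OR-predicate and all 3^6 verdict vectors against a strict-majority
oracle.

Pathogenic variants covered by fewer than 20 reads are flagged for
orthogonal (Sanger) confirmation (`validation_min_coverage`, strict `<`).

## Compatibility filtering and diagnosis

A candidate survives filtering when (a) its gene's phenotype groups
intersect the patient's compatible-phenotype set, and (b) if the pedigree
pattern is AD or XL, the gene carries that mode. AR and simplex pedigrees
exclude nothing on mode, since simplex cases can resolve to any mode. The
conjunction (a) AND (b) is the default; `compatibility_mode: or` relaxes it,
because the source wording ("not compatible with known phenotypes or
inheritance patterns") is grammatically ambiguous and AND is the stricter,
more clinically defensible reading.

The compatibility map ships as editable YAML
(`data/phenotype_compatibility.yaml`) and is deliberately permissive within
the photoreceptor and macular disease families (RP additionally compatible
with choroideraemia, Bietti, Usher and CSNB genes), reflecting documented
mimicry.

Diagnosis rules per gene:

- AD gene: one pathogenic variant → definite (AD). For dual-mode (AD+AR)
  genes the AD rule fires only under an AD pedigree; otherwise the AR rule
  applies. Without this gate every single heterozygote in a dual-mode gene
  (e.g. RP1) would auto-resolve as definite AD, contradicting the existence
  of recessive compound heterozygotes in such genes.
- XL gene: hemizygous male, or homozygous female → definite (XL). A single
  het in an XL-only gene in a female is a carrier by default
  (`xl_het_female: affected` overrides), following standard hemizygosity
  logic.
- AR gene: two *distinct* het pathogenic variants (compound het, assumed in
  trans — no parental genotypes are used; two het calls at one locus
  collapse to one allele) or one homozygote → definite (AR); exactly one
  het → possible.

Across genes the best status wins (definite > possible > none); ties break
by summed rationale strength (KNOWN = 3, ACMG = 2, TRUNCATING = 2,
CONSENSUS = 1 per causal variant), then alphabetically. Runners-up are
written to a secondary report rather than discarded.

Refinement: the diagnostic gene sets the refined inheritance mode. The
clinical diagnosis is kept when it is among the gene's phenotype groups;
otherwise it is revised to the gene's most specific group under the
shipped specificity ordering (so an RP presentation with causal *CHM*
variants becomes choroideraemia).

## Summarisation conventions

Percentages are printed to one decimal place with round-half-up
(implemented with `decimal.Decimal`, not float rounding). Phenotype
denominators use the post-refinement diagnosis by default
(`denominator: clinical` switches to presenting diagnoses). Mutant-allele
tallies count het/hemi causal variants once and homozygotes twice,
de-duplicated per patient; novelty splits by the `previously_reported`
flag; consequence distributions are over allele copies, with splicing kept
separate from truncating classes. Gene rankings use solved patients in the
stratum as the denominator, descending by count with alphabetical ties.
Possible-diagnosis variants are excluded from causal-allele tallies (they
are reported separately), since a possible diagnosis is not a causal
finding.

## Capture QC

Coverage evenness over the target, with per-base coverages c_b and mean C:
E = 100 · mean(min(c_b, C))/C. The source describes the metric only by
citation, so this truncated-mean form is adopted as the working definition;
the equivalent threshold-sum form 100 · Σ_{i=1..⌊C⌋} F(i)/C (F(i) =
fraction of bases ≥ i×) is implemented as an internal cross-check. The two
agree exactly when C is an integer and within 100/C percentage points
otherwise; `evenness_score` asserts that bound at run time. E ≤ 100 with
equality iff coverage is constant, and E is invariant under integer scaling
of the profile.

Other metrics: arithmetic mean depth; percentage of bases ≥ t× (t = 20 by
default); duplication rate = 100 · duplicates/total reads; callset
sensitivity = 100 · |test ∩ ref| / |ref| and PPV = 100 · |test ∩ ref| /
|test| against any supplied reference callset (no particular truth set is
assumed). Coverage input is per-base TSV or half-open BedGraph-like
intervals. Published per-product capture values depend on the sequencing
libraries and are not reproduced here; only the metric definitions are in
scope.

## Synthetic cohorts

The generator plants causal genotypes per inheritance pattern (AD het, AR
compound het, AR hom, AR single het → possible, XL hemizygous male, XL
homozygous female) on a toy exome coordinate system — each gene owns a
disjoint window; XL genes sit on chrX — and surrounds them with benign
background variants (Poisson count per patient, default mean 6; consequence
mix 40 % synonymous / 50 % missense / 10 % other; ACMG uncertain-or-benign;
at most 3 damaging votes) that cannot satisfy any pathogenicity criterion.
Causal variants pass QC by construction (depth 30–80×, het VAF 0.40–0.60)
and carry annotations that satisfy the rules: previously reported variants
get the known flag plus ACMG pathogenic; novel variants get ACMG likely
pathogenic plus a 5/6 damaging consensus. Noise knobs degrade this
deliberately: QC-failure injection (depth 8, 1 alt read), second-allele
dropout for compound hets, and per-criterion annotation dropout
(`drop_known_rate`, `drop_acmg_rate`, `drop_consensus_rate`). Everything is
driven by one `numpy` RNG seeded from `rng_seed`; outputs are byte-stable.

The `paper_counts` preset fixes a 168-patient cohort: 86 definite (60 AR
compound het, 18 AD het, 7 XL hemizygous males, 1 XL homozygous female —
147 causal alleles), 30 possible, 52 unsolved, distributed over phenotype
strata (107 post-refinement RP with 58 solved, 13 of them USH2A; 9/10
STGD via ABCA4; etc.), with exact allele quotas (89 missense, 26 nonsense,
25 frameshift, 7 splicing; 96 reported / 51 novel) and a pedigree layout
in which 55 of the definite diagnoses redefine the inheritance pattern,
including 37 solved simplex cases resolving 35 AR / 1 AD / 1 XL. Three
showcase reclassifications are planted: RP→choroideraemia (CHM),
RP→Bietti (CYP4V2) and STGD→CORD (CNGB3).

What the simulator does **not** emulate: realistic allele-frequency
spectra, linkage, trio structure, annotation errors beyond the explicit
dropout knobs, transcript-level ambiguity, or sequence context (HGVS
strings are schematic). Passing the closed-loop tests therefore
demonstrates that the *rules* are implemented exactly as specified and
that the bookkeeping is correct — not that the rules themselves have any
particular sensitivity/specificity on real exomes.

## Problem sizes and determinism

The test suite and the acceptance script run the 168-patient preset
(≈ 1,100 calls) plus recovery cohorts of 230 planted patients and
brute-force oracle sweeps (10,000 random QC calls, 3^6 verdict vectors,
490-point classification grid, 100 random coverage profiles); the whole
suite completes in a few seconds on one CPU. Hypothesis profiles are
derandomised, and all simulation randomness is seed-driven.

## Known limitations

- Compound-het phase is assumed (in trans) — without parental genotypes a
  cis pair would be over-called as definite.
- The diagnosis engine reports one causal gene per patient (runners-up in a
  side report); true dual diagnoses are not modelled.
- The shipped panel is a representative 46-gene subset for demonstration
  and testing; real analyses should supply a current full panel file, as
  panel content drifts over time.
- ACMG classes, predictor verdicts and the known-disease flag are consumed
  as annotations; none of the upstream tools are reimplemented.
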