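# Methods

## Problem setting

Recurrent gliomas treated with temozolomide (TMZ) can escape therapy through
at least three routes: retained MGMT expression when the *MGMT* promoter is
unmethylated, mismatch-repair-driven DNA hypermutation, and — the focus of
this package — genomic rearrangements that fuse the intact *MGMT* coding
sequence to another gene's promoter. The pipeline screens RNA-seq fusion
candidates, annotates the survivors structurally, determines per-patient
alteration status, assembles a cohort landscape, and tests whether the three
resistance mechanisms are mutually exclusive.

## Coordinate model and fusion annotation

Transcripts are modelled as ordered exon lists in GTF convention (1-based,
inclusive), with exons stored in transcription order and a genomic CDS-start
coordinate. Breakpoints are `chrom:pos:strand` with `pos` the exonic base
adjacent to the junction: the last retained base of the 5′ (donor) gene and
the first retained base of the 3′ (acceptor) gene. Chromosome names are
normalised by stripping a `chr` prefix. When several transcripts exist per
gene, the one with the longest CDS is used (ties broken by lexicographic
transcript id).

The signed distance from a breakpoint to the start codon is
`offset(ATG) − offset(breakpoint)` in spliced-mRNA coordinates, so a
breakpoint 12 nt upstream of the ATG returns +12 — the configuration shared
by the recurrent MGMT fusions, whose MGMT-side breakpoint falls on the
exon-2 acceptor boundary. Annotation rules:

- `partner_cds_nt` — spliced CDS bases of the 5′ partner at or upstream of
  its breakpoint (0 when the partner contributes only 5′UTR).
- `five_prime_utr_swap` — partner_cds_nt = 0 **and** the 3′ breakpoint at or
  upstream of the 3′ ATG (right CDS intact): a pure promoter exchange.
- `chimeric_in_frame` / `chimeric_out_of_frame` — coding contribution tested
  by `partner_cds_nt mod 3`. This is sufficient because the MGMT-side offset
  (+12) is itself divisible by 3, leaving the acceptor frame unshifted; the
  rule is applied generally and a non-multiple-of-3 acceptor offset would
  surface as out-of-frame at the protein level regardless.
- `unresolved` — either breakpoint off an exon boundary (or intronic); a
  diagnostic is attached instead of raising.
- Domain retention: with an intact 3′ CDS every 3′-gene domain is retained;
  with an in-frame truncation a domain survives iff its first residue lies
  strictly downstream of the lost ⌈lost nt/3⌉ residues; out-of-frame or
  unresolved events retain nothing. Default MGMT domain ranges
  (DNA-binding 92–135, methyltransferase 136–176 on the 207-aa protein) are
  approximate packaged values and can be overridden by TSV.

Filtering precedence is fixed — normal-tissue pair, mitochondrial gene
(`MT-` prefix), uncharacterized gene (clone-style regexes such as `^LOC\d+`,
`^C\d+orf\d+$`, `^LINC\d+`, `^A[CLP]\d{6}`, `-AS\d*$`), paralog pair — so
audits are deterministic when a candidate matches several rules. The
normal-tissue and paralog lists are small packaged defaults (pluggable);
they are illustrative resources, not exhaustive catalogues. No minimum
junction/spanning read support is applied by default.

## Hotspot calls

IDH1 R132 / IDH2 R172 status comes from pileup base counts at packaged
GRCh37 hotspot coordinates. Depth < 5 ⇒ NA (not assessable) — this
availability rule is the fixed part of the procedure and is independent of
allele content. Otherwise a site is mutant iff non-reference reads satisfy
both `min_alt_reads` (default 2) and `min_vaf` (default 0.10); these two
thresholds are deliberate package choices exposed as configuration, since
only the availability rule is canonical. At depth 20 and a heterozygous
variant fraction of 0.5 the miss probability is P[Bin(20,0.5) < 2] ≈ 2×10⁻⁵,
so planted genotypes recover with error well under 1%. 1p/19q co-deletion
and hypermutation are ingested as upstream yes/no/NA calls and never
recomputed.

## Expression and cohort statistics

RPKM = counts × 10⁹ / (gene length × total mapped reads). Because the pooled
cohort mixes sequencing batches, MGMT expression is re-centred as a
within-cohort Z-score, z = (x − mean)/SD with sample SD (ddof = 1), applied
to log2(RPKM + 1); cohorts with n < 2 or zero spread give NA. Alteration
frequencies use assay-specific denominators (NA patients never enter a
denominator); percentages are rounded half-up to one decimal. The fusion
frequency carries an exact Clopper–Pearson interval
(lower = Beta⁻¹(α/2; x, n−x+1), 0 at x=0; upper = Beta⁻¹(1−α/2; x+1, n−x),
1 at x=n); Clopper–Pearson was chosen because among the standard interval
constructions (Wilson, Wald, Clopper–Pearson) it alone reproduces the
1.1–5.6% bounds for 7/252. Group comparisons use the Wilcoxon rank-sum test
(exact null for combined n ≤ 20 without ties, otherwise the tie-corrected
normal approximation) and the two-sided Fisher exact test.

## Mutual-exclusivity bootstrap

The test statistic is coverage: the number of patients carrying at least one
of the alterations (per-patient, so a patient with two fusions counts once).
The null holds every alteration's positive count fixed and reassigns its
positives uniformly at random without replacement, independently across
alterations; by default each alteration is permuted within its own assayed
set (a methylation-untested patient cannot receive a methylation label),
with `scope="all"` available to permute over the whole cohort — the original
analysis does not state which convention it used, so both are implemented.
Coverage is always counted over all patients. With the default 10,000
replicates:

- `p_value = #{coverage > observed} / n_reps` — the published
  strictly-greater convention, so a maximally exclusive configuration
  yields exactly 0 (reported as < 1/n_reps).
- `p_smoothed = (#{>} + 1)/(n_reps + 1)` — add-one version, never 0.
- `p_tie_inclusive = #{coverage ≥ observed} / n_reps` — counts ties.

Calibration: coverage is a discrete statistic with non-negligible atoms.
The tie-inclusive p is superuniform under the null
(P(p ≤ t) = P(C ≥ d_t) ≤ t for d_t = min{c : P(C ≥ c) ≤ t}) and is the
variant to use when type-I control matters. The strictly-greater p is *not*
superuniform — excluding ties removes the atom at the observed value, and
in the degenerate single-alteration case it is identically 0. It is kept as
the primary output because it is the published formula; the test suite
demonstrates both facts (the tie-inclusive superuniformity property passes;
the analogous check on the strictly-greater p fails by construction and is
retained as documentation of the miscalibration).

`enumerate_exclusivity_exact` computes the same tail probability by
exhausting all joint placements (refusing > 10⁶ states) and is the
independent oracle: on random small instances the bootstrap at 50,000
replicates agrees within 4 Monte-Carlo SEs. Calibration checks on the
bootstrap estimate additionally allow a 4-SE Monte-Carlo blur term, since
even an exactly calibrated p-value estimated from finite replicates smears
across thresholds adjacent to an atom.

## Synthetic study design

The default generator reproduces the shape of the emulated cohort: n = 252
patients from five source cohorts (proportions 105/72/42/28/5), alteration
marginals 7 fusion / 27 hypermutation / 52 hypomethylation with the
methylation assay restricted to a uniformly random 136-patient subset, and
disjoint positive sets (`overlap_mode` also offers `independent` and
`nested` so both null and alternative regimes are testable). Eight distinct
fusion events are planted in the seven fusion patients (one patient carries
two), using partner models that mirror the observed structures: three pure
5′UTR swaps and five in-frame coding contributions, every breakpoint on an
exon boundary, and the MGMT-like acceptor boundary 12 nt upstream of the
ATG (configurable). IDH marginals default to 94 mutant / 245 assessable
(seven patients receive sub-threshold depth), 1p/19q to 23/245. Expression
is log2-Gaussian with class shifts (+2 for fusion and hypomethylation, −2
for hypermutation, noise SD 1) plus a per-cohort batch offset (SD 0.5) that
the within-cohort Z-score is designed to absorb; the default sex ratio
(female fraction 0.45) is a placeholder, not an estimated quantity.

All generators are pure functions of (config, seed) using a single
`numpy.random.default_rng` stream per call; the pipeline derives per-stage
seeds from one top-level seed via `SeedSequence.spawn`. What the synthetic
data does **not** emulate: read-level sequencing noise, fusion-caller
artefact spectra beyond the four decoy classes, correlated missingness of
assays, real expression distributions, or survival. Passing tests therefore
establish correctness of the computation on inputs with known truth, not
performance of upstream callers on real data.

## Sizes and runtimes

Defaults keep everything interactive on one CPU: the full test suite runs in
well under a minute (the heaviest pieces being 50 oracle-vs-bootstrap
instances at 50,000 replicates, 1000-seed Wilcoxon calibration, and
1000-draw exclusivity calibration at 5000 replicates each, all vectorised),
and the acceptance script completes in seconds. The headline bootstrap
(n = 252, 10,000 replicates) takes ~20 ms.

## Known limitations

- The in-frame rule keys on the 5′ contribution only; acceptor-side frame
  shifts from non-boundary breakpoints are reported as `unresolved` rather
  than frame-annotated.
- The packaged normal-tissue/paralog/domain resources are small defaults
  meant for synthetic studies and smoke tests; production use should supply
  curated tables.
- The strictly-greater bootstrap p is anticonservative near atoms of the
  coverage distribution (see above); use `p_tie_inclusive` for calibrated
  inference.
- Reproduction on the real cohort requires the original per-patient
  supplementary table and is out of scope here; the synthetic defaults
  reproduce its printed marginal structure instead.
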