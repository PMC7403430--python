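# fusionscape

Analysis pipeline for detecting and interpreting **MGMT gene fusions** as a
mechanism of temozolomide (TMZ) resistance in recurrent gliomas.

TMZ kills glioma cells through the O6-methylguanine DNA lesion, which the
repair enzyme MGMT reverses directly; epigenetic silencing of *MGMT* by
promoter hypermethylation is the classic biomarker of TMZ response. In a
subset of TMZ-treated recurrent tumors, however, genomic rearrangements
place the intact *MGMT* coding sequence under a foreign promoter — the
transcriptomic breakpoint sits on the *MGMT* exon-2 acceptor boundary, 12 nt
upstream of the start codon, so the full protein (methyltransferase and
DNA-binding domains included) is overexpressed and the tumor resists TMZ
regardless of its promoter methylation. `fusionscape` implements the
computational side of that analysis as a tested, reusable pipeline:

- **Fusion screening** — ingest fusion-caller candidate TSVs and remove, in
  fixed precedence, fusions seen in normal tissues, fusions involving
  mitochondrial genes, fusions involving uncharacterized genes, and fusions
  of two paralogs, with a per-candidate audit trail.
- **Structural annotation** — place breakpoints on spliced transcript
  coordinates from an Ensembl-dialect GTF, measure the distance to the start
  codon, classify each fusion as a 5′UTR promoter swap or an (in/out of
  frame) chimera, and test domain retention. A 5′-partner coding
  contribution of length *L* keeps the chimera in frame iff *L* ≡ 0 (mod 3).
- **Hotspot calling** — IDH1 R132 / IDH2 R172 status from RNA-seq pileup
  base counts, with the availability rule: depth < 5 ⇒ NA.
- **Cohort landscape** — RPKM expression, within-cohort Z-scores (batch
  control), assay-specific alteration frequencies, the exact
  Clopper–Pearson binomial CI
  (lower = Beta⁻¹(α/2; x, n−x+1), upper = Beta⁻¹(1−α/2; x+1, n−x)),
  Fisher exact and Wilcoxon rank-sum comparisons.
- **Mutual exclusivity** — a bootstrap test on the *coverage* statistic (the
  number of patients carrying ≥1 of hypomethylation, hypermutation, fusion):
  each replicate reassigns every alteration's positive count uniformly at
  random within its assayed set, and
  P = #{replicates with coverage > observed} / 10,000,
  with an exact enumeration oracle for small instances and a tie-inclusive
  variant for calibrated type-I control.
- **Synthetic data** — seeded generators for every input (cohort tables
  with exact marginal counts and controllable overlap, gene models, fusion
  candidates with decoys of each filtered class, pileups, expression), so
  the whole pipeline is testable without any sequencing data.

## Worked example

```python
from fusionscape.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(outdir="out", seed=1,
                                     simulate={"n_patients": 252}))
ci = report["fusion_ci"]
print(report["stages"]["assemble"])
print(round(100 * ci["lower"], 1), round(100 * ci["upper"], 1))
print(report["exclusivity"]["observed_coverage"],
      report["exclusivity"]["p_value"])
```

prints

```
{'patients': 252, 'distinct_fusions': 8, 'fusion_patients': 7}
1.1 5.6
86 0.0
```

i.e. on the default synthetic study — 252 patients, eight planted fusions in
seven patients, disjoint alteration marginals 7/27/52 — the pipeline
recovers seven fusion-positive patients (~3% of the cohort; exact 95% CI
1.1–5.6%), and the three resistance alterations jointly cover 86 patients, a
coverage no random reassignment of the same marginals can exceed, so the
exclusivity bootstrap returns P = 0 (< 10⁻⁴ at 10,000 replicates).

The same stages are exposed on the command line:

```
fusionscape simulate --seed 1 --outdir sim
fusionscape screen-fusions --candidates sim/fusion_candidates.tsv --out audit.tsv
fusionscape call-idh --pileup sim/pileup.tsv --out idh.csv
fusionscape run --config config.yaml
fusionscape test-exclusivity --landscape out/landscape.tsv --reps 10000 --seed 1
```

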