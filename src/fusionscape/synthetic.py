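"""Synthetic inputs with known ground truth for every pipeline stage.

The study this pipeline emulates pooled 252 TMZ-treated recurrent gliomas from
five source cohorts and scored three resistance-related alterations per
patient: MGMT promoter hypomethylation (assayed in a 136-patient subset), DNA
hypermutation, and MGMT gene fusion. The generators here reproduce that shape
— a multi-cohort patient table with configurable marginal counts and overlap
structure, gene models with known exon/CDS layout, fusion-candidate tables
with planted true events plus one decoy per filtered class, hotspot pileups
with controlled depth and allele fraction, and an MGMT expression column whose
class effects (fusion/hypomethylated high, hypermutated low) are configurable.

Every generator is a pure function of (config, seed): the same seed yields a
byte-identical table. Truth is returned alongside each table so downstream
recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_model import TranscriptModel, genomic_to_mrna, mrna_to_genomic

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "TranscriptConfig",
    "DepthLaw",
    "ExpressionEffects",
    "InfeasibleSpecError",
    "default_cohort_spec",
    "default_gene_model_config",
    "gen_cohort",
    "gen_gene_models",
    "gen_fusion_candidates",
    "gen_pileups",
    "gen_expression",
]

# Marginals of the emulated cohort: 252 patients, 7 fusion-positive,
# 27 hypermutated, 52 hypomethylated among 136 with a methylation assay.
DEFAULT_N = 252
DEFAULT_COUNTS = {"fusion": 7, "hypermutation": 27, "hypomethylation": 52}
DEFAULT_ASSAYED = {"fusion": 252, "hypermutation": 252, "hypomethylation": 136}
# Source-cohort proportions mirror the pooled design (105/72/42/28/5 of 252).
DEFAULT_COHORTS = [
    ("CGGA_new", 105 / 252),
    ("SMC", 72 / 252),
    ("CGGA_hu", 42 / 252),
    ("CGGA_bao", 28 / 252),
    ("TCGA", 5 / 252),
]


class InfeasibleSpecError(ValueError):
    """The requested cohort configuration cannot be realised."""


@dataclass
class SyntheticCohortSpec:
    n_patients: int = DEFAULT_N
    alteration_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    assayed_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ASSAYED))
    overlap_mode: str = "disjoint"
    cohort_labels: list[tuple[str, float]] = field(default_factory=lambda: list(DEFAULT_COHORTS))
    female_fraction: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InfeasibleSpecError("n_patients must be positive")
        if self.overlap_mode not in {"disjoint", "independent", "nested"}:
            raise InfeasibleSpecError(f"unknown overlap_mode {self.overlap_mode!r}")
        for name, count in self.alteration_counts.items():
            assayed = self.assayed_counts.get(name, self.n_patients)
            if not 0 <= count <= assayed <= self.n_patients:
                raise InfeasibleSpecError(
                    f"{name}: need count <= assayed <= n "
                    f"({count} <= {assayed} <= {self.n_patients})"
                )
        if abs(sum(p for _, p in self.cohort_labels) - 1.0) > 1e-9:
            raise InfeasibleSpecError("cohort proportions must sum to 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InfeasibleSpecError("female_fraction must be in [0, 1]")
        if self.overlap_mode == "disjoint":
            if sum(self.alteration_counts.values()) > self.n_patients:
                raise InfeasibleSpecError(
                    "disjoint mode: alteration counts sum to "
                    f"{sum(self.alteration_counts.values())} > n = {self.n_patients}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation, fully recoverable for assertions."""

    statuses: pd.DataFrame | None = None  # bool per patient x alteration
    assayed: pd.DataFrame | None = None  # bool mask, same shape
    fusion_events: pd.DataFrame | None = None
    hotspot_genotypes: dict | None = None
    expression_effects: "ExpressionEffects | None" = None


def default_cohort_spec(seed: int = 0, overlap_mode: str = "disjoint") -> SyntheticCohortSpec:
    return SyntheticCohortSpec(seed=seed, overlap_mode=overlap_mode)


def _largest_remainder_counts(n: int, proportions: list[float]) -> list[int]:
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    for i in sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True):
        if sum(counts) == n:
            break
        counts[i] += 1
    return counts


def gen_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the per-patient cohort table and its ground truth.

    Columns: patient_id, cohort, sex, then one {yes,no,NA} column per
    alteration. Exactly ``alteration_counts[a]`` patients are positive among
    the ``assayed_counts[a]`` assayed ones; the rest of the assayed are "no"
    and non-assayed patients are "NA". Overlap between the positive sets is
    controlled by ``overlap_mode`` (disjoint / independent / nested).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patients = [f"P{i:04d}" for i in range(1, n + 1)]

    cohort_sizes = _largest_remainder_counts(n, [p for _, p in spec.cohort_labels])
    cohort_col = np.repeat([name for name, _ in spec.cohort_labels], cohort_sizes)
    rng.shuffle(cohort_col)

    n_female = int(round(spec.female_fraction * n))
    sex_col = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex_col)

    names = list(spec.alteration_counts)
    assayed_idx: dict[str, np.ndarray] = {}
    for name in names:
        k = spec.assayed_counts.get(name, n)
        assayed_idx[name] = (
            np.arange(n) if k >= n else np.sort(rng.choice(n, size=k, replace=False))
        )

    positives: dict[str, np.ndarray] = {}
    if spec.overlap_mode == "disjoint":
        # most constrained assay first, so the default 52-of-136 methylation
        # marginal stays feasible alongside the fully-assayed alterations
        used: set[int] = set()
        for name in sorted(names, key=lambda a: len(assayed_idx[a])):
            pool = np.setdiff1d(assayed_idx[name], np.fromiter(used, int, len(used)))
            want = spec.alteration_counts[name]
            if len(pool) < want:
                raise InfeasibleSpecError(
                    f"disjoint mode: only {len(pool)} assayed patients free for "
                    f"{name}, need {want}"
                )
            chosen = rng.choice(pool, size=want, replace=False)
            positives[name] = np.sort(chosen)
            used.update(chosen.tolist())
    elif spec.overlap_mode == "independent":
        for name in names:
            positives[name] = np.sort(
                rng.choice(assayed_idx[name], size=spec.alteration_counts[name], replace=False)
            )
    else:  # nested: later (smaller) positive sets drawn inside earlier ones
        union: set[int] = set()
        for name in sorted(names, key=lambda a: spec.alteration_counts[a], reverse=True):
            want = spec.alteration_counts[name]
            preferred = np.fromiter(sorted(union.intersection(assayed_idx[name].tolist())), int)
            take = min(want, len(preferred))
            chosen = list(rng.choice(preferred, size=take, replace=False)) if take else []
            if take < want:
                rest = np.setdiff1d(assayed_idx[name], np.fromiter(chosen, int, len(chosen)))
                chosen.extend(rng.choice(rest, size=want - take, replace=False).tolist())
            positives[name] = np.sort(np.asarray(chosen, dtype=int))
            union.update(positives[name].tolist())

    table = pd.DataFrame({"patient_id": patients, "cohort": cohort_col, "sex": sex_col})
    status_bool = pd.DataFrame(False, index=patients, columns=names)
    assay_mask = pd.DataFrame(False, index=patients, columns=names)
    for name in names:
        col = np.full(n, "NA", dtype=object)
        col[assayed_idx[name]] = "no"
        col[positives[name]] = "yes"
        table[name] = col
        assay_mask.iloc[assayed_idx[name], assay_mask.columns.get_loc(name)] = True
        status_bool.iloc[positives[name], status_bool.columns.get_loc(name)] = True

    truth = SyntheticTruth(statuses=status_bool, assayed=assay_mask)
    return table, truth


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class TranscriptConfig:
    """Blueprint for one synthetic transcript.

    The CDS starts at spliced offset ``utr5_length + 1``; a ``utr5_length``
    at or beyond the mRNA end is rejected (CDS start outside exons).
    """

    gene_name: str
    exon_lengths: list[int]
    utr5_length: int
    cds_length: int
    strand: str = "+"
    chrom: str = "10"
    intron_length: int = 500
    biotype: str = "protein_coding"


def default_gene_model_config(mgmt_utr_offset: int = 12) -> list[TranscriptConfig]:
    """Fixture set emulating the recurrent promoter-swap fusions.

    The MGMT-like model places the exon-2 acceptor boundary
    ``mgmt_utr_offset`` nt upstream of the start codon (default 12, the
    offset shared by all the recurrent-glioma MGMT fusions). Partner models
    cover a UTR-only 5' contribution (SAR1A/RPH3A/CTBP2-like) and coding 5'
    contributions (BTRC/NFYC-like), including a minus-strand gene.
    """
    return [
        # exon 1 fully 5'UTR; ATG sits mgmt_utr_offset nt into exon 2
        TranscriptConfig("MGMT", [100, 500], utr5_length=100 + mgmt_utr_offset, cds_length=300),
        # breakpoint at the exon-1 donor contributes 5'UTR only
        TranscriptConfig("SAR1A", [120, 400], utr5_length=170, cds_length=300),
        TranscriptConfig("RPH3A", [90, 300], utr5_length=150, cds_length=120),
        TranscriptConfig("CTBP2", [150, 350], utr5_length=200, cds_length=240),
        # coding 5' contributions, exon-1 CDS length a multiple of 3 (in-frame)
        TranscriptConfig("BTRC", [200, 200, 400], utr5_length=80, cds_length=600),
        TranscriptConfig("NFYC", [180, 240, 300], utr5_length=60, cds_length=510, strand="-"),
        TranscriptConfig("CAPZB", [150, 300], utr5_length=90, cds_length=240),
        TranscriptConfig("GLRX3", [130, 280], utr5_length=70, cds_length=180, strand="-"),
        TranscriptConfig("FAM175B", [160, 300], utr5_length=100, cds_length=240),
    ]


def gen_gene_models(
    config: list[TranscriptConfig] | None = None, seed: int = 0
) -> list[TranscriptModel]:
    """Build transcript models from blueprints, laid out along one contig."""
    config = default_gene_model_config() if config is None else config
    rng = np.random.default_rng(seed)
    models = []
    cursor = 1000
    for i, cfg in enumerate(config):
        mrna_len = sum(cfg.exon_lengths)
        if cfg.utr5_length + 1 > mrna_len:
            raise ValueError(
                f"{cfg.gene_name}: CDS start at offset {cfg.utr5_length + 1} "
                f"outside the {mrna_len}-nt mRNA"
            )
        if cfg.utr5_length + cfg.cds_length > mrna_len:
            raise ValueError(f"{cfg.gene_name}: CDS extends beyond mRNA end")
        exons = []
        pos = cursor
        for length in cfg.exon_lengths:
            exons.append((pos, pos + length - 1))
            pos += length + cfg.intron_length + int(rng.integers(0, 100))
        cursor = pos + 10_000
        model = TranscriptModel(
            transcript_id=f"T{i:03d}_{cfg.gene_name}",
            gene_id=f"G{i:03d}",
            gene_name=cfg.gene_name,
            chrom=cfg.chrom,
            strand=cfg.strand,
            exons=exons,
            biotype=cfg.biotype,
        )
        model.cds_start_genomic = mrna_to_genomic(model, cfg.utr5_length + 1)
        model.cds_end_genomic = mrna_to_genomic(model, cfg.utr5_length + cfg.cds_length)
        model.__post_init__()  # re-validate with CDS attached
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Fusion candidates

FUSION_COLUMNS = [
    "FusionName",
    "LeftGene",
    "LeftBreakpoint",
    "RightGene",
    "RightBreakpoint",
    "JunctionReadCount",
    "SpanningFragCount",
    "SampleID",
]

# one decoy archetype per filtered class; coordinates are arbitrary
_DECOY_ARCHETYPES = {
    "normal_tissue": ("TFG", "GPR128", "3:100447000:+", "3:100332000:+"),
    "mitochondrial": ("MT-CO1", "NDUFA1", "MT:6500:+", "X:119000000:+"),
    "uncharacterized": ("LOC100131234", "EGFR", "1:5000000:+", "7:55200000:+"),
    "paralog": ("HSPA1A", "HSPA1B", "6:31783000:+", "6:31795000:+"),
}


def gen_fusion_candidates(
    models: list[TranscriptModel],
    n_true: int = 1,
    decoy_config: dict[str, int] | None = None,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Fusion-candidate table: planted MGMT fusions plus labelled decoys.

    True events join a partner model's exon-1 donor boundary to the MGMT-like
    model's exon-2 acceptor boundary (both breakpoints on exon boundaries).
    Decoy classes mirror the filter's removal rules. The returned frame
    carries a ``TruthClass`` column ("true" or the decoy class name).
    """
    decoy_config = (
        {cls: 1 for cls in _DECOY_ARCHETYPES} if decoy_config is None else decoy_config
    )
    rng = np.random.default_rng(seed)
    by_name = {m.gene_name: m for m in models}
    mgmt = by_name.get("MGMT")
    if n_true and mgmt is None:
        raise ValueError("models must include an MGMT-like transcript for true events")
    partners = [m for m in models if m.gene_name != "MGMT"]
    rows = []
    for i in range(n_true):
        partner = partners[i % len(partners)]
        left_donor = partner.exons[0][1] if partner.strand == "+" else partner.exons[0][0]
        acc_exon = mgmt.exons[1] if len(mgmt.exons) > 1 else mgmt.exons[0]
        right_acceptor = acc_exon[0] if mgmt.strand == "+" else acc_exon[1]
        sample = (
            sample_ids[i % len(sample_ids)] if sample_ids else f"P{i + 1:04d}"
        )
        rows.append(
            {
                "FusionName": f"{partner.gene_name}--MGMT",
                "LeftGene": partner.gene_name,
                "LeftBreakpoint": f"{partner.chrom}:{left_donor}:{partner.strand}",
                "RightGene": "MGMT",
                "RightBreakpoint": f"{mgmt.chrom}:{right_acceptor}:{mgmt.strand}",
                "JunctionReadCount": int(rng.poisson(20) + 1),
                "SpanningFragCount": int(rng.poisson(10) + 1),
                "SampleID": sample,
                "TruthClass": "true",
            }
        )
    for cls, count in decoy_config.items():
        if cls not in _DECOY_ARCHETYPES:
            raise ValueError(f"unknown decoy class {cls!r}")
        left, right, lbp, rbp = _DECOY_ARCHETYPES[cls]
        for j in range(count):
            rows.append(
                {
                    "FusionName": f"{left}--{right}",
                    "LeftGene": left,
                    "LeftBreakpoint": lbp,
                    "RightGene": right,
                    "RightBreakpoint": rbp,
                    "JunctionReadCount": int(rng.poisson(20) + 1),
                    "SpanningFragCount": int(rng.poisson(10) + 1),
                    "SampleID": f"P{j + 1:04d}",
                    "TruthClass": cls,
                }
            )
    return pd.DataFrame(rows, columns=FUSION_COLUMNS + ["TruthClass"])


# ---------------------------------------------------------------------------
# Pileups


@dataclass
class DepthLaw:
    """Per-site sequencing depth distribution and heterozygous allele fraction."""

    mean_depth: float = 50.0
    distribution: str = "poisson"  # or "constant"
    allele_fraction: float = 0.5

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.distribution == "constant":
            return np.full(size, int(self.mean_depth))
        if self.distribution == "poisson":
            return rng.poisson(self.mean_depth, size=size)
        raise ValueError(f"unknown depth distribution {self.distribution!r}")


def gen_pileups(
    genotypes: dict[str, dict[str, str]],
    depth_law: DepthLaw | None = None,
    seed: int = 0,
    hotspot_defs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pileup base counts at the IDH hotspot positions.

    ``genotypes`` maps sample_id -> {hotspot key ("IDH1_R132" / "IDH2_R172")
    -> "mutant" | "wildtype"}. Mutant samples draw variant reads as
    Binomial(depth, allele_fraction); wildtype samples have zero variant
    reads. Depths come from ``depth_law``.
    """
    from .variant_status import load_hotspot_definitions

    depth_law = depth_law or DepthLaw()
    defs = load_hotspot_definitions() if hotspot_defs is None else hotspot_defs
    defs = defs.set_index(defs["gene"] + "_" + defs["codon"])
    rng = np.random.default_rng(seed)
    rows = []
    for sample in sorted(genotypes):
        for key in sorted(genotypes[sample]):
            status = genotypes[sample][key]
            if key not in defs.index:
                raise ValueError(f"unknown hotspot {key!r}")
            site = defs.loc[key]
            depth = int(depth_law.draw(rng, 1)[0])
            alt_reads = (
                int(rng.binomial(depth, depth_law.allele_fraction))
                if status == "mutant"
                else 0
            )
            counts = {b: 0 for b in "ACGT"}
            counts[site["ref"]] = depth - alt_reads
            counts[site["alt"]] += alt_reads
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": str(site["chrom"]),
                    "pos": int(site["pos"]),
                    "ref": site["ref"],
                    **counts,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionEffects:
    """Class effects on log2 MGMT expression.

    Fusion-positive and hypomethylated patients are shifted up, hypermutated
    patients down (the lowest-expressing class); additive Gaussian noise per
    patient plus an optional per-cohort batch offset that the within-cohort
    Z-score downstream is meant to absorb.
    """

    baseline_log2: float = 3.0
    fusion_shift: float = 2.0
    hypomethylation_shift: float = 2.0
    hypermutation_shift: float = -2.0
    noise_sd: float = 1.0
    batch_sd: float = 0.5


def gen_expression(
    cohort_table: pd.DataFrame,
    effects: ExpressionEffects | None = None,
    seed: int = 0,
) -> pd.Series:
    """MGMT expression (linear RPKM) per patient with planted class effects."""
    effects = effects or ExpressionEffects()
    rng = np.random.default_rng(seed)
    n = len(cohort_table)
    log2 = np.full(n, effects.baseline_log2, dtype=float)

    for column, shift in (
        ("fusion", effects.fusion_shift),
        ("hypomethylation", effects.hypomethylation_shift),
        ("hypermutation", effects.hypermutation_shift),
    ):
        if column in cohort_table.columns:
            log2 += np.where(cohort_table[column].to_numpy() == "yes", shift, 0.0)

    cohorts = cohort_table["cohort"].to_numpy()
    offsets = {c: rng.normal(0.0, effects.batch_sd) for c in sorted(set(cohorts))}
    log2 += np.array([offsets[c] for c in cohorts])
    log2 += rng.normal(0.0, effects.noise_sd, size=n)
    return pd.Series(
        np.power(2.0, log2), index=cohort_table["patient_id"].to_numpy(), name="mgmt_rpkm"
    )


# ---------------------------------------------------------------------------
# File emission (dialects match the downstream readers)


def write_simulation(outdir, spec: SyntheticCohortSpec | None = None, seed: int = 0) -> dict:
    """Generate one full synthetic study and write every pipeline input.

    Returns a dict of the paths written plus the truth objects.
    """
    from .gene_model import write_gtf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or default_cohort_spec(seed=seed)
    rng = np.random.default_rng(seed)

    cohort, truth = gen_cohort(spec)
    models = gen_gene_models(seed=seed)
    fusion_samples = (
        truth.statuses.index[truth.statuses["fusion"]].tolist()
        if "fusion" in truth.statuses.columns
        else None
    )
    # one fusion patient carries two distinct events, so with the default
    # 7 fusion-positive patients the candidate list plants 8 true fusions
    n_true = len(fusion_samples) + 1 if fusion_samples else 1
    n_true = min(n_true, sum(m.gene_name != "MGMT" for m in models))
    candidates = gen_fusion_candidates(
        models, n_true=n_true, seed=seed, sample_ids=fusion_samples
    )

    # IDH marginals: a small subset of patients is unassessable (hotspot depth
    # below the availability cutoff); the assessable remainder carries a fixed
    # number of mutants (defaults emulate 94 mutant / 245 assessable of 252)
    n = len(cohort)
    n_idh_na = min(7, max(0, n - 1))
    n_idh_mut = min(94, n - n_idh_na)
    order = rng.permutation(n)
    na_patients = set(cohort["patient_id"].iloc[order[:n_idh_na]])
    mut_patients = set(cohort["patient_id"].iloc[order[n_idh_na : n_idh_na + n_idh_mut]])
    genotypes = {
        pid: {"IDH1_R132": "mutant" if pid in mut_patients else "wildtype"}
        for pid in cohort["patient_id"]
    }
    truth.hotspot_genotypes = genotypes
    pileups = gen_pileups(genotypes, seed=seed)
    shallow = pileups["sample_id"].isin(na_patients)
    for base in "ACGT":
        pileups.loc[shallow, base] = 0
    pileups.loc[shallow & (pileups["ref"] == "C"), "C"] = 3  # depth 3 < cutoff
    pileups.loc[shallow & (pileups["ref"] != "C"), pileups.columns[-1]] = 3

    expression = gen_expression(cohort, seed=seed)

    # 1p/19q marginals: same NA subset, fixed positive count (default 23/245)
    codel_order = rng.permutation(n)
    codel_yes = set(
        cohort["patient_id"].iloc[[i for i in codel_order if cohort["patient_id"].iloc[i] not in na_patients][: min(23, n)]]
    )
    codel = [
        "NA" if pid in na_patients else ("yes" if pid in codel_yes else "no")
        for pid in cohort["patient_id"]
    ]
    upstream = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "codel_1p19q": codel,
            "hypermutation": cohort["hypermutation"].replace({"NA": "no"}),
        }
    )

    paths = {
        "cohort_csv": outdir / "cohort.csv",
        "fusion_tsv": outdir / "fusion_candidates.tsv",
        "gtf": outdir / "genes.gtf",
        "pileup_tsv": outdir / "pileup.tsv",
        "upstream_csv": outdir / "upstream_calls.csv",
        "expression_csv": outdir / "expression.csv",
    }
    cohort.to_csv(paths["cohort_csv"], index=False)
    candidates.drop(columns=["TruthClass"]).to_csv(paths["fusion_tsv"], sep="\t", index=False)
    candidates.to_csv(outdir / "fusion_truth.tsv", sep="\t", index=False)
    write_gtf(models, paths["gtf"])
    pileups.to_csv(paths["pileup_tsv"], sep="\t", index=False)
    upstream.to_csv(paths["upstream_csv"], index=False)
    expression.rename_axis("patient_id").reset_index().to_csv(
        paths["expression_csv"], index=False
    )
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth, "models": models}
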