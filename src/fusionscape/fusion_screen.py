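"""Fusion-candidate ingestion, filtering, and structural annotation.

Candidates come from an RNA-seq fusion caller as a TSV of junctions. Four
removal rules are applied, in fixed precedence, to discard the classes of
artefactual or uninteresting calls: (1) fusions also seen in normal tissues,
(2) fusions involving mitochondrial genes, (3) fusions involving
uncharacterized genes (clone-style names), (4) fusions between two paralogs.
Survivors are annotated against gene models: how much 5'-partner CDS is
retained, where the 3'-gene breakpoint sits relative to its start codon,
whether the downstream reading frame is preserved, and whether the protein
domains of the 3' gene survive in the chimera.

The recurrent MGMT fusions motivating this module share one structure: the
MGMT-side breakpoint falls on the exon-2 acceptor boundary, 12 nt upstream of
the start codon, so the entire MGMT coding sequence rides along. When the
partner contributes only its 5'UTR the event is a pure promoter swap
(category ``five_prime_utr_swap``); when it contributes coding sequence the
chimera is in-frame iff that contribution is divisible by three (the +12
MGMT-side offset is itself a multiple of three, so the acceptor frame is
unperturbed).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from math import ceil

import pandas as pd

from .gene_model import (
    NotExonicError,
    TranscriptModel,
    distance_to_start_codon,
    exon_boundary_class,
    genomic_to_mrna,
    normalize_chrom,
)

__all__ = [
    "FusionCandidate",
    "FusionAnnotation",
    "FilterAudit",
    "REMOVAL_REASONS",
    "DEFAULT_UNCHARACTERIZED_PATTERNS",
    "DEFAULT_MITO_PREFIXES",
    "read_fusion_candidates",
    "load_normal_blacklist",
    "load_paralog_pairs",
    "load_mgmt_domains",
    "filter_candidates",
    "annotate_fusion",
    "fusion_patient_summary",
]

logger = logging.getLogger(__name__)

REMOVAL_REASONS = ("normal_tissue", "mitochondrial", "uncharacterized", "paralog", "retained")

# clone-style / positional gene names treated as uncharacterized
DEFAULT_UNCHARACTERIZED_PATTERNS = (
    r"^LOC\d+",
    r"^LINC\d+",
    r"^C\d+orf\d+$",
    r"^A[CLP]\d{6}",
    r"-AS\d*$",
)
DEFAULT_MITO_PREFIXES = ("MT-",)

REQUIRED_COLUMNS = [
    "FusionName",
    "LeftGene",
    "LeftBreakpoint",
    "RightGene",
    "RightBreakpoint",
    "JunctionReadCount",
    "SpanningFragCount",
    "SampleID",
]


@dataclass(frozen=True)
class FusionCandidate:
    """One caller-reported fusion junction."""

    left_gene: str
    right_gene: str
    left_breakpoint: tuple[str, int, str]  # (chrom, pos, strand)
    right_breakpoint: tuple[str, int, str]
    junction_reads: int
    spanning_frags: int
    sample_id: str

    def __post_init__(self):
        if not self.left_gene or not self.right_gene:
            raise ValueError("gene names must be non-empty")
        if self.left_breakpoint[1] <= 0 or self.right_breakpoint[1] <= 0:
            raise ValueError("breakpoint positions must be positive")

    @property
    def name(self) -> str:
        return f"{self.left_gene}--{self.right_gene}"


@dataclass
class FusionAnnotation:
    """Structural classification of one retained fusion."""

    candidate: FusionCandidate
    category: str  # five_prime_utr_swap | chimeric_in_frame | chimeric_out_of_frame | unresolved
    partner_cds_nt: int
    right_offset_to_start_codon: int | None
    right_cds_intact: bool
    domains_retained: dict[str, bool] = field(default_factory=dict)
    breakpoint_on_exon_boundary: tuple[bool, bool] = (False, False)
    diagnostic: str = ""


@dataclass
class FilterAudit:
    """Removal reason per input candidate, in input order."""

    reasons: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {r: self.reasons.count(r) for r in REMOVAL_REASONS}


def _parse_breakpoint(raw: str) -> tuple[str, int, str]:
    parts = str(raw).split(":")
    if len(parts) != 3 or parts[2] not in {"+", "-"}:
        raise ValueError(f"unparsable breakpoint {raw!r} (expected chrom:pos:strand)")
    return normalize_chrom(parts[0]), int(parts[1]), parts[2]


def read_fusion_candidates(path) -> list[FusionCandidate]:
    """Read a caller-style fusion TSV into candidates.

    Missing required columns raise a schema error; an unparsable breakpoint
    raises with the 1-based file line number.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    candidates = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            candidates.append(
                FusionCandidate(
                    left_gene=str(row.LeftGene),
                    right_gene=str(row.RightGene),
                    left_breakpoint=_parse_breakpoint(row.LeftBreakpoint),
                    right_breakpoint=_parse_breakpoint(row.RightBreakpoint),
                    junction_reads=int(row.JunctionReadCount),
                    spanning_frags=int(row.SpanningFragCount),
                    sample_id=str(row.SampleID),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return candidates


def _load_pair_tsv(name: str) -> set[frozenset]:
    ref = importlib_resources.files("fusionscape.resources") / name
    with importlib_resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    return {frozenset((a, b)) for a, b in zip(frame["gene_a"], frame["gene_b"])}


def load_normal_blacklist(path=None) -> set[frozenset]:
    """Gene pairs recurrently fused in normal tissue (packaged default list)."""
    if path is not None:
        frame = pd.read_csv(path, sep="\t")
        return {frozenset((a, b)) for a, b in zip(frame["gene_a"], frame["gene_b"])}
    return _load_pair_tsv("normal_tissue_fusions.tsv")


def load_paralog_pairs(path=None) -> set[frozenset]:
    if path is not None:
        frame = pd.read_csv(path, sep="\t")
        return {frozenset((a, b)) for a, b in zip(frame["gene_a"], frame["gene_b"])}
    return _load_pair_tsv("paralog_pairs.tsv")


def load_mgmt_domains(path=None) -> list[tuple[str, int, int]]:
    """MGMT protein domains as (name, aa_start, aa_end).

    Packaged defaults cover the DNA-binding and methyltransferase domains
    with approximate residue ranges on the 207-aa protein; supply a TSV
    (gene, domain, aa_start, aa_end) to override.
    """
    if path is not None:
        frame = pd.read_csv(path, sep="\t")
    else:
        ref = importlib_resources.files("fusionscape.resources") / "mgmt_domains.tsv"
        with importlib_resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    return [(r["domain"], int(r["aa_start"]), int(r["aa_end"])) for _, r in frame.iterrows()]


def filter_candidates(
    candidates: list[FusionCandidate],
    normal_blacklist: set[frozenset] | None = None,
    paralog_pairs: set[frozenset] | None = None,
    uncharacterized_patterns: list[str] | None = None,
    mito_prefixes: list[str] | None = None,
) -> tuple[list[FusionCandidate], FilterAudit]:
    """Apply the four removal rules in fixed precedence.

    Precedence: normal_tissue -> mitochondrial -> uncharacterized -> paralog;
    a candidate matching several rules is audited under the first. Filtering
    is monotone and idempotent.
    """
    normal = load_normal_blacklist() if normal_blacklist is None else normal_blacklist
    paralogs = load_paralog_pairs() if paralog_pairs is None else paralog_pairs
    patterns = [
        re.compile(p)
        for p in (uncharacterized_patterns or DEFAULT_UNCHARACTERIZED_PATTERNS)
    ]
    prefixes = tuple(mito_prefixes or DEFAULT_MITO_PREFIXES)

    def reason(c: FusionCandidate) -> str:
        pair = frozenset((c.left_gene, c.right_gene))
        if pair in normal:
            return "normal_tissue"
        if any(g.startswith(prefixes) for g in (c.left_gene, c.right_gene)):
            return "mitochondrial"
        if any(p.search(g) for p in patterns for g in (c.left_gene, c.right_gene)):
            return "uncharacterized"
        if pair in paralogs:
            return "paralog"
        return "retained"

    audit = FilterAudit([reason(c) for c in candidates])
    retained = [c for c, r in zip(candidates, audit.reasons) if r == "retained"]
    return retained, audit


def annotate_fusion(
    candidate: FusionCandidate,
    left_model: TranscriptModel,
    right_model: TranscriptModel,
    domains: list[tuple[str, int, int]] | None = None,
) -> FusionAnnotation:
    """Classify a fusion structurally against its two gene models.

    ``partner_cds_nt`` counts spliced CDS bases of the 5' partner retained
    upstream of (and including) its breakpoint; 0 means a UTR-only
    contribution. ``right_offset_to_start_codon`` is positive when the 3'
    breakpoint lies upstream of the ATG, in which case the 3' CDS is intact.
    A breakpoint off an exon boundary (or intronic) yields ``unresolved``
    with a diagnostic rather than an exception.
    """
    domains = load_mgmt_domains() if domains is None else domains
    left_pos = candidate.left_breakpoint[1]
    right_pos = candidate.right_breakpoint[1]

    left_class = exon_boundary_class(left_model, left_pos)
    right_class = exon_boundary_class(right_model, right_pos)
    on_boundary = (left_class == "donor_boundary", right_class == "acceptor_boundary")

    if left_class == "not_exonic" or right_class == "not_exonic":
        return FusionAnnotation(
            candidate,
            category="unresolved",
            partner_cds_nt=0,
            right_offset_to_start_codon=None,
            right_cds_intact=False,
            domains_retained={name: False for name, _, _ in domains},
            breakpoint_on_exon_boundary=on_boundary,
            diagnostic=f"breakpoint not exonic (left={left_class}, right={right_class})",
        )

    # 5'-partner retained CDS length (spliced)
    partner_cds_nt = 0
    if left_model.is_coding:
        bp_off = genomic_to_mrna(left_model, left_pos).offset
        cds_off = genomic_to_mrna(left_model, left_model.cds_start_genomic).offset
        cds_end_off = genomic_to_mrna(left_model, left_model.cds_end_genomic).offset
        partner_cds_nt = max(0, min(bp_off, cds_end_off) - cds_off + 1)

    try:
        right_offset = distance_to_start_codon(right_model, right_pos)
    except NotExonicError:  # pragma: no cover - guarded above
        right_offset = None
    right_cds_intact = right_offset is not None and right_offset >= 0

    if not all(on_boundary):
        category = "unresolved"
        diagnostic = "breakpoint(s) off exon boundary"
    elif partner_cds_nt == 0 and right_cds_intact:
        category = "five_prime_utr_swap"
        diagnostic = ""
    elif partner_cds_nt % 3 == 0:
        category = "chimeric_in_frame"
        diagnostic = ""
    else:
        category = "chimeric_out_of_frame"
        diagnostic = ""

    # domain retention on the 3' gene
    lost_nt = 0 if right_cds_intact else (-right_offset if right_offset is not None else None)
    domains_retained = {}
    for name, aa_start, aa_end in domains:
        if category == "unresolved":
            domains_retained[name] = False
        elif right_cds_intact:
            domains_retained[name] = True
        elif category == "chimeric_out_of_frame" or lost_nt is None:
            domains_retained[name] = False
        else:
            domains_retained[name] = aa_start > ceil(lost_nt / 3)

    return FusionAnnotation(
        candidate,
        category=category,
        partner_cds_nt=partner_cds_nt,
        right_offset_to_start_codon=right_offset,
        right_cds_intact=right_cds_intact,
        domains_retained=domains_retained,
        breakpoint_on_exon_boundary=on_boundary,
        diagnostic=diagnostic,
    )


def fusion_patient_summary(
    annotations: list[FusionAnnotation], cohort_table: pd.DataFrame
) -> tuple[int, int, pd.DataFrame]:
    """Distinct-fusion and fusion-positive-patient tallies.

    A patient with two distinct fusions counts once in the patient tally.
    Annotations whose sample_id is not a cohort patient are skipped with a
    warning. Returns (n_distinct_fusions, n_patients, per-patient frame).
    """
    known = set(cohort_table["patient_id"].astype(str))
    fusions: set[str] = set()
    per_patient: dict[str, list[str]] = {}
    for ann in annotations:
        sample = ann.candidate.sample_id
        if sample not in known:
            logger.warning("unknown sample_id %r in fusion annotations; row skipped", sample)
            continue
        fusions.add(ann.candidate.name)
        per_patient.setdefault(sample, []).append(ann.candidate.name)
    frame = pd.DataFrame(
        {
            "patient_id": cohort_table["patient_id"].astype(str),
        }
    )
    frame["fusion_positive"] = frame["patient_id"].map(
        lambda p: "yes" if p in per_patient else "no"
    )
    frame["fusion_names"] = frame["patient_id"].map(
        lambda p: ",".join(sorted(set(per_patient.get(p, []))))
    )
    return len(fusions), len(per_patient), frame
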