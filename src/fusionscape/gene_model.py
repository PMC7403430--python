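"""Transcript models from Ensembl-dialect GTF and coordinate queries.

Fusion breakpoints reported by RNA-seq callers are genomic coordinates; to
classify a fusion structurally we need to place each breakpoint on the spliced
mRNA of the involved transcript, measure its distance to the start codon, and
decide whether it falls on an exon boundary. This module provides the
:class:`TranscriptModel` container plus those queries.

Conventions: GTF coordinates, 1-based inclusive. Exons are stored in
transcription order (reverse genomic order for minus-strand transcripts).
Chromosome names are normalised by stripping a leading ``chr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TranscriptModel",
    "MrnaCoordinate",
    "GtfParseError",
    "NotExonicError",
    "NonCodingError",
    "read_gtf",
    "write_gtf",
    "genomic_to_mrna",
    "mrna_to_genomic",
    "distance_to_start_codon",
    "exon_boundary_class",
    "select_canonical",
]


class GtfParseError(ValueError):
    """Malformed GTF content; message carries the offending line number."""


class NotExonicError(ValueError):
    """A genomic position does not fall inside any exon of the transcript."""


class NonCodingError(ValueError):
    """Operation requires a CDS but the transcript has none."""


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class MrnaCoordinate:
    """1-based offset in the spliced mRNA of one transcript."""

    transcript_id: str
    offset: int


@dataclass
class TranscriptModel:
    """Exon/CDS structure of a single transcript.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive,
    non-overlapping, ordered 5'->3' in transcription order.
    ``cds_start_genomic`` is the genomic coordinate of the first coding base
    (the A of ATG in mRNA orientation); ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start_genomic: int | None = None
    cds_end_genomic: int | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e}")
        genomic_sorted = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        # enforce transcription order
        self.exons = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if self.cds_start_genomic is not None and not self.contains(self.cds_start_genomic):
            raise ValueError(
                f"CDS start {self.cds_start_genomic} outside exons of {self.transcript_id}"
            )

    @property
    def mrna_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic is not None

    def contains(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos <= e for s, e in self.exons)


def genomic_to_mrna(model: TranscriptModel, genomic_pos: int) -> MrnaCoordinate:
    """Map an exonic genomic position to its 1-based spliced-mRNA offset."""
    offset = 0
    for s, e in model.exons:
        if s <= genomic_pos <= e:
            within = (genomic_pos - s) if model.strand == "+" else (e - genomic_pos)
            return MrnaCoordinate(model.transcript_id, offset + within + 1)
        offset += e - s + 1
    raise NotExonicError(
        f"position {model.chrom}:{genomic_pos} is not exonic in {model.transcript_id}"
    )


def mrna_to_genomic(model: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_mrna`."""
    if not 1 <= offset <= model.mrna_length:
        raise ValueError(f"offset {offset} outside mRNA of length {model.mrna_length}")
    remaining = offset - 1
    for s, e in model.exons:
        length = e - s + 1
        if remaining < length:
            return s + remaining if model.strand == "+" else e - remaining
        remaining -= length
    raise AssertionError("unreachable")


def distance_to_start_codon(model: TranscriptModel, genomic_breakpoint: int) -> int:
    """Signed nt distance from a breakpoint to the start codon on the mRNA.

    Positive means the breakpoint lies upstream (5') of the ATG by that many
    nucleotides; the promoter-swap fusions place the acceptor breakpoint 12 nt
    upstream of the MGMT start codon, so such a breakpoint returns +12.
    """
    if not model.is_coding:
        raise NonCodingError(f"{model.transcript_id} has no CDS")
    cds = genomic_to_mrna(model, model.cds_start_genomic).offset
    bp = genomic_to_mrna(model, genomic_breakpoint).offset
    return cds - bp


def exon_boundary_class(model: TranscriptModel, genomic_pos: int) -> str:
    """Classify a position: donor_boundary / acceptor_boundary / internal / not_exonic.

    Donor = last base of an exon in transcription order; acceptor = first base.
    Single-base exons classify as donor_boundary (donor checked first).
    """
    for s, e in model.exons:
        if not s <= genomic_pos <= e:
            continue
        first, last = (s, e) if model.strand == "+" else (e, s)
        if genomic_pos == last:
            return "donor_boundary"
        if genomic_pos == first:
            return "acceptor_boundary"
        return "internal"
    return "not_exonic"


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect)

_ATTR_KEYS = ("gene_id", "gene_name", "transcript_id", "gene_biotype")


def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon/CDS features from an Ensembl-dialect GTF into transcript models.

    One model per ``transcript_id``; unknown feature types are ignored.
    Raises :class:`GtfParseError` with the line number on malformed lines.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, raw_attrs = fields
            if feature not in {"exon", "CDS"}:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            attrs = _parse_attributes(raw_attrs)
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(f"{path}: line {lineno}: missing transcript_id attribute")
            meta.setdefault(tid, {}).update(
                {k: attrs[k] for k in _ATTR_KEYS if k in attrs}
            )
            meta[tid].setdefault("chrom", normalize_chrom(chrom))
            meta[tid].setdefault("strand", strand)
            (exons if feature == "exon" else cds).setdefault(tid, []).append((start_i, end_i))

    models = []
    for tid, info in meta.items():
        tid_exons = exons.get(tid)
        tid_cds = cds.get(tid)
        if tid_cds and not tid_exons:
            raise ValueError(f"transcript {tid} has CDS features but no exons")
        if not tid_exons:
            continue
        cds_start = cds_end = None
        if tid_cds:
            lo = min(s for s, _ in tid_cds)
            hi = max(e for _, e in tid_cds)
            cds_start, cds_end = (lo, hi) if info["strand"] == "+" else (hi, lo)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info.get("gene_id", tid),
                gene_name=info.get("gene_name", info.get("gene_id", tid)),
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tid_exons,
                cds_start_genomic=cds_start,
                cds_end_genomic=cds_end,
                biotype=info.get("gene_biotype", "protein_coding"),
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write transcript models back out as Ensembl-dialect GTF (exon + CDS)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; gene_name "{m.gene_name}"; '
                f'transcript_id "{m.transcript_id}"; gene_biotype "{m.biotype}";'
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\tfusionscape\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                lo, hi = sorted((m.cds_start_genomic, m.cds_end_genomic))
                for s, e in sorted(m.exons):
                    cs, ce = max(s, lo), min(e, hi)
                    if cs <= ce:
                        fh.write(
                            f"{m.chrom}\tfusionscape\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\t{attrs}\n"
                        )


def select_canonical(models: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Pick one transcript per gene for annotation.

    Longest CDS wins; non-coding transcripts rank below coding; ties break on
    lexicographic transcript_id.
    """

    def cds_len(m: TranscriptModel) -> int:
        if not m.is_coding:
            return -1
        a = genomic_to_mrna(m, m.cds_start_genomic).offset
        b = genomic_to_mrna(m, m.cds_end_genomic).offset
        return abs(b - a) + 1

    chosen: dict[str, TranscriptModel] = {}
    for m in sorted(models, key=lambda m: m.transcript_id):
        cur = chosen.get(m.gene_name)
        if cur is None or cds_len(m) > cds_len(cur):
            chosen[m.gene_name] = m
    return chosen
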