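"""IDH hotspot calling from pileup base counts; ingestion of upstream calls.

IDH1 R132 / IDH2 R172 status is determined directly from RNA-seq pileups: a
hotspot position covered by fewer than five reads is not assessable and is
reported NA; otherwise the site is called mutant when the non-reference read
support clears both an absolute count and a variant-allele-fraction floor.
The availability rule (>= 5 reads, else NA) is the fixed part of the
procedure; the mutant-call thresholds are explicit configuration
(min_alt_reads=2, min_vaf=0.1 by default).

1p/19q co-deletion and hypermutation are produced by dedicated upstream tools
(copy-number prediction from expression, mutation-burden classification) and
are ingested here as per-patient yes/no/NA calls, not recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources as importlib_resources

import pandas as pd

__all__ = [
    "PileupSite",
    "HotspotCall",
    "MIN_DEPTH",
    "load_hotspot_definitions",
    "read_pileup",
    "call_hotspot",
    "call_cohort_hotspots",
    "ingest_upstream_calls",
]

logger = logging.getLogger(__name__)

MIN_DEPTH = 5  # below this the hotspot is not assessable (NA)

_BASES = ("A", "C", "G", "T")
_STATUS_TOKENS = {"yes", "no", "NA"}


@dataclass(frozen=True)
class PileupSite:
    """Base counts at one genomic position for one sample."""

    sample_id: str
    chrom: str
    pos: int
    ref_base: str
    base_counts: dict

    def __post_init__(self):
        for base in _BASES:
            if self.base_counts.get(base, 0) < 0:
                raise ValueError(
                    f"negative count for {base} at {self.chrom}:{self.pos} "
                    f"({self.sample_id})"
                )

    @property
    def depth(self) -> int:
        return sum(self.base_counts.get(b, 0) for b in _BASES)

    @property
    def alt_reads(self) -> int:
        return self.depth - self.base_counts.get(self.ref_base, 0)


@dataclass(frozen=True)
class HotspotCall:
    sample_id: str
    gene: str
    codon: str
    status: str  # mutant | wildtype | NA
    depth: int
    variant_fraction: float | None


def load_hotspot_definitions() -> pd.DataFrame:
    """Packaged IDH hotspot table (GRCh37 coordinates, canonical alt allele)."""
    ref = importlib_resources.files("fusionscape.resources") / "idh_hotspots.tsv"
    with importlib_resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_pileup(path) -> list[PileupSite]:
    """Read a pre-tallied pileup TSV (sample_id, chrom, pos, ref, A, C, G, T)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample_id", "chrom", "pos", "ref", *_BASES}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing pileup columns {sorted(missing)}")
    sites = []
    for row in frame.itertuples(index=False):
        sites.append(
            PileupSite(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_base=str(row.ref),
                base_counts={b: int(getattr(row, b)) for b in _BASES},
            )
        )
    return sites


def call_hotspot(
    site: PileupSite,
    hotspot_def,
    min_depth: int = MIN_DEPTH,
    min_alt_reads: int = 2,
    min_vaf: float = 0.1,
) -> HotspotCall:
    """Call one hotspot site.

    depth < min_depth -> NA. Otherwise mutant iff non-reference reads meet
    both ``min_alt_reads`` and ``min_vaf``; else wildtype.
    """
    if int(hotspot_def["pos"]) != site.pos or str(hotspot_def["chrom"]) != site.chrom:
        raise ValueError(
            f"site {site.chrom}:{site.pos} does not match hotspot "
            f"{hotspot_def['gene']} {hotspot_def['codon']} at "
            f"{hotspot_def['chrom']}:{hotspot_def['pos']}"
        )
    depth = site.depth
    if depth < min_depth:
        return HotspotCall(
            site.sample_id, hotspot_def["gene"], hotspot_def["codon"], "NA", depth, None
        )
    alt = site.alt_reads
    vaf = alt / depth
    status = "mutant" if (alt >= min_alt_reads and vaf >= min_vaf) else "wildtype"
    return HotspotCall(
        site.sample_id, hotspot_def["gene"], hotspot_def["codon"], status, depth, vaf
    )


def call_cohort_hotspots(
    sites: list[PileupSite],
    hotspot_defs: pd.DataFrame | None = None,
    **thresholds,
) -> pd.DataFrame:
    """Call every (sample, hotspot) pair present in a pileup.

    Returns a frame with sample_id, gene, codon, status, depth,
    variant_fraction. Sites not matching any defined hotspot are ignored.
    """
    defs = load_hotspot_definitions() if hotspot_defs is None else hotspot_defs
    by_pos = {(str(r["chrom"]), int(r["pos"])): r for _, r in defs.iterrows()}
    calls = []
    for site in sites:
        definition = by_pos.get((site.chrom, site.pos))
        if definition is None:
            continue
        calls.append(call_hotspot(site, definition, **thresholds))
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "codon": c.codon,
                "status": c.status,
                "depth": c.depth,
                "variant_fraction": c.variant_fraction,
            }
            for c in calls
        ],
        columns=["sample_id", "gene", "codon", "status", "depth", "variant_fraction"],
    )


def ingest_upstream_calls(
    table: pd.DataFrame, known_patients: set[str] | None = None
) -> pd.DataFrame:
    """Validate and attach upstream 1p/19q and hypermutation calls.

    ``table`` needs a patient_id column plus status columns with values in
    {yes, no, NA}. Patients not in ``known_patients`` (when given) are
    skipped with a warning.
    """
    if "patient_id" not in table.columns:
        raise ValueError("upstream calls need a patient_id column")
    status_cols = [c for c in table.columns if c != "patient_id"]
    for col in status_cols:
        bad = set(table[col].astype(str)) - _STATUS_TOKENS
        if bad:
            raise ValueError(f"invalid status token(s) {sorted(bad)} in column {col!r}")
    out = table.copy()
    out["patient_id"] = out["patient_id"].astype(str)
    if known_patients is not None:
        unknown = ~out["patient_id"].isin(known_patients)
        if unknown.any():
            logger.warning(
                "skipping %d upstream-call rows for unknown patients: %s",
                int(unknown.sum()),
                ", ".join(out.loc[unknown, "patient_id"].head(5)),
            )
            out = out[~unknown]
    return out.reset_index(drop=True)
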