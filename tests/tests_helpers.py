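"""Shared helpers for building candidate objects from generator frames."""

from fusionscape.fusion_screen import FusionCandidate


def _parse_bp(raw):
    chrom, pos, strand = raw.split(":")
    return (chrom, int(pos), strand)


def candidates_from_frame(table):
    return [
        FusionCandidate(
            r.LeftGene, r.RightGene, _parse_bp(r.LeftBreakpoint),
            _parse_bp(r.RightBreakpoint), r.JunctionReadCount,
            r.SpanningFragCount, r.SampleID,
        )
        for r in table.itertuples(index=False)
    ]
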