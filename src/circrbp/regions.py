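"""Sequence-region extraction around backsplice junctions.

Five region classes drive the motif analysis: the circRNA body, the 5'/3'
flanking windows (the "flanking introns", taken as fixed-length genomic
windows adjacent to the backsplice coordinates), and the two 100-nt
junction boundary windows (intron side + circRNA side).  All sequences are
returned in transcript orientation: minus-strand records are
reverse-complemented and their up/downstream sides swapped accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import CircRecord, GenomeStore, reverse_complement

REGION_KINDS = ("flank5", "boundary5", "body", "boundary3", "flank3")


@dataclass
class RegionSet:
    circ_id: str
    region_kind: str  # one of REGION_KINDS
    sequence: str  # transcript orientation
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.region_kind not in REGION_KINDS:
            raise ValueError(f"unknown region_kind {self.region_kind!r}")
        total = sum(e - s for _, s, e, _ in self.intervals)
        if self.intervals and total != len(self.sequence):
            raise ValueError(
                f"{self.circ_id}/{self.region_kind}: sequence length {len(self.sequence)} "
                f"!= summed interval length {total}"
            )


def extract_body(circ: CircRecord, genome: GenomeStore, use_blocks: bool = True) -> RegionSet:
    """Spliced circRNA body sequence, 5'->3' in transcript orientation."""
    if circ.end > genome.lengths[circ.chrom]:
        raise ValueError(f"{circ.circ_id}: interval exceeds chromosome {circ.chrom}")
    if use_blocks and circ.exon_blocks:
        if any(be <= bs for bs, be in circ.exon_blocks):
            raise ValueError(f"{circ.circ_id}: empty exon block")
        blocks = circ.exon_blocks
    else:
        blocks = [(circ.start, circ.end)]
    seq = "".join(genome.fetch(circ.chrom, bs, be) for bs, be in blocks)
    intervals = [(circ.chrom, bs, be, circ.strand) for bs, be in blocks]
    if circ.strand == "-":
        seq = reverse_complement(seq)
        intervals = intervals[::-1]
    return RegionSet(circ.circ_id, "body", seq, intervals)


def extract_flanks(circ: CircRecord, genome: GenomeStore, flank_len: int) -> tuple[RegionSet, RegionSet]:
    """Fixed-length windows up/downstream of the backsplice junction.

    flank5 is the ``flank_len`` bases upstream of the backsplice acceptor in
    transcript orientation, flank3 the bases downstream of the donor.
    Windows are truncated (and flagged) at chromosome ends.
    """
    chrom_len = genome.lengths[circ.chrom]
    left_start = max(0, circ.start - flank_len)
    left = genome.fetch(circ.chrom, left_start, circ.start)
    right_end = min(chrom_len, circ.end + flank_len)
    right = genome.fetch(circ.chrom, circ.end, right_end)
    left_iv = (circ.chrom, left_start, circ.start, circ.strand)
    right_iv = (circ.chrom, circ.end, right_end, circ.strand)
    left_trunc = len(left) < flank_len
    right_trunc = len(right) < flank_len
    if circ.strand == "+":
        flank5 = RegionSet(circ.circ_id, "flank5", left, [left_iv], truncated=left_trunc)
        flank3 = RegionSet(circ.circ_id, "flank3", right, [right_iv], truncated=right_trunc)
    else:
        flank5 = RegionSet(circ.circ_id, "flank5", reverse_complement(right), [right_iv], truncated=right_trunc)
        flank3 = RegionSet(circ.circ_id, "flank3", reverse_complement(left), [left_iv], truncated=left_trunc)
    return flank5, flank3


def extract_boundaries(
    circ: CircRecord, genome: GenomeStore, boundary_len: int, flank_len: int | None = None
) -> tuple[RegionSet, RegionSet]:
    """Junction boundary windows: intron-side + circRNA-side sequence.

    boundary5 = last ``boundary_len`` nt of flank5 followed by the first
    ``boundary_len`` nt of the (spliced) body; boundary3 symmetric at the
    donor end.  Short bodies/flanks truncate the corresponding side and set
    the ``truncated`` flag.
    """
    if flank_len is None:
        flank_len = boundary_len
    body = extract_body(circ, genome, use_blocks=True)
    flank5, flank3 = extract_flanks(circ, genome, flank_len)

    in5 = flank5.sequence[-boundary_len:] if flank5.sequence else ""
    body5 = body.sequence[:boundary_len]
    b5_trunc = len(in5) < boundary_len or len(body5) < boundary_len
    boundary5 = RegionSet(circ.circ_id, "boundary5", in5 + body5, truncated=b5_trunc)

    body3 = body.sequence[-boundary_len:]
    in3 = flank3.sequence[:boundary_len] if flank3.sequence else ""
    b3_trunc = len(in3) < boundary_len or len(body3) < boundary_len
    boundary3 = RegionSet(circ.circ_id, "boundary3", body3 + in3, truncated=b3_trunc)
    return boundary5, boundary3


def extract_all_regions(
    circs, genome: GenomeStore, flank_len: int = 1000, boundary_len: int = 50, use_blocks: bool = True
) -> dict[str, dict[str, RegionSet]]:
    """All five region classes for every circRNA: kind -> circ_id -> RegionSet."""
    out: dict[str, dict[str, RegionSet]] = {kind: {} for kind in REGION_KINDS}
    for circ in circs:
        body = extract_body(circ, genome, use_blocks=use_blocks)
        flank5, flank3 = extract_flanks(circ, genome, flank_len)
        boundary5, boundary3 = extract_boundaries(circ, genome, boundary_len, flank_len)
        for rs in (body, flank5, flank3, boundary5, boundary3):
            out[rs.region_kind][circ.circ_id] = rs
    return out


def write_regions_fasta(regions: dict[str, dict[str, RegionSet]], path) -> None:
    """FASTA export with headers ``circ_id|region_kind|chrom:start-end(strand)``."""
    with open(path, "w") as fh:
        for kind in REGION_KINDS:
            for circ_id, rs in regions.get(kind, {}).items():
                if rs.intervals:
                    chrom, s, e, strand = rs.intervals[0]
                    loc = f"{chrom}:{s}-{e}({strand})"
                else:
                    loc = "composite"
                fh.write(f">{circ_id}|{kind}|{loc}\n{rs.sequence}\n")
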