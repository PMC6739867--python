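"""Read placement and coverage normalization.

A deliberately minimal deterministic aligner (exact 21-mer seed, ungapped
extension, bounded mismatches) places synthetic reads on contig or vector
references; real-data users can import SAM produced by any external mapper
instead, and every downstream stage consumes :class:`AlignmentRecord`
regardless of origin.

Mapping quality is binary: 60 for a unique best placement, 0 for a tie
(reported at the lexicographically smallest reference/position).  The
downstream thresholds (MQ > 10 for linkage, MQ >= 25 for genotyping) only
need to separate unique from ambiguous placements.

Coverage uses RPBM -- reads per base-pair per million library reads:
``mapped_read_count / reference_length / (total_library_reads / 1e6)``.
RPBM counts mapped *reads* (each mate once), not read-bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .synthetic_library import reverse_complement

DEFAULT_SEED_K = 21
MAPQ_UNIQUE = 60
MAPQ_AMBIGUOUS = 0


@dataclass(frozen=True)
class AlignmentRecord:
    """One read placed ungapped on a reference.

    ``sequence`` and ``base_qualities`` are reference-oriented (reverse
    complemented for minus-strand placements), as in SAM.  ``fragment_length``
    is the outer distance (leftmost start to rightmost end) for proper pairs.
    """

    read_id: str
    reference_id: str
    start: int
    strand: str
    n_mismatches: int
    mapping_quality: int
    sequence: str
    base_qualities: str
    is_read1: bool = True
    is_paired: bool = False
    proper_pair: bool = False
    fragment_length: int | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start

    def spans(self, pos: int) -> bool:
        """True if the alignment covers >= 1 base on each side of ``pos``."""
        return self.start < pos < self.end


class ReferenceIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, references: dict[str, str], k: int = DEFAULT_SEED_K):
        if len(set(references)) != len(references):
            raise ValueError("duplicate reference ids")
        self.k = k
        self.references = dict(references)
        self.lengths = {rid: len(s) for rid, s in references.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for rid in sorted(references):
            seq = references[rid]
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i:i + k], []).append((rid, i))

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _place_single(index: ReferenceIndex, seq: str,
                  max_mismatches: int) -> list[tuple[str, int, str, int]]:
    """All best placements of one read: (ref, start, strand, mismatches)."""
    k = index.k
    if len(seq) < k:
        return []
    candidates: set[tuple[str, int, str]] = set()
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in {0, len(s) - k}:
            for rid, pos in index.seed_hits(s[off:off + k]):
                start = pos - off
                if 0 <= start and start + len(s) <= index.lengths[rid]:
                    candidates.add((rid, start, strand))
    placements = []
    for rid, start, strand in candidates:
        s = seq if strand == "+" else reverse_complement(seq)
        nm = _hamming(s, index.references[rid][start:start + len(s)])
        if nm <= max_mismatches:
            placements.append((rid, start, strand, nm))
    if not placements:
        return []
    best = min(p[3] for p in placements)
    return sorted(p for p in placements if p[3] == best)


def _record(read_id: str, seq: str, qual: str,
            placement: tuple[str, int, str, int], mapq: int,
            **kw) -> AlignmentRecord:
    rid, start, strand, nm = placement
    if strand == "-":
        seq = reverse_complement(seq)
        qual = qual[::-1]
    return AlignmentRecord(read_id=read_id, reference_id=rid, start=start,
                           strand=strand, n_mismatches=nm,
                           mapping_quality=mapq, sequence=seq,
                           base_qualities=qual, **kw)


def align_reads(reads: Iterable, references: dict[str, str],
                mode: str = "single", max_mismatches: int = 3,
                min_fragment: int = 0, k: int = DEFAULT_SEED_K
                ) -> list[AlignmentRecord]:
    """Place reads on references.

    ``mode="single"``: ``reads`` yields (read_id, sequence, quality); each
    read is reported at its unique best placement (MQ 60) or the smallest of
    tied best placements (MQ 0).

    ``mode="paired_no_mixed"``: ``reads`` yields
    (pair_id, seq1, qual1, seq2, qual2); only pairs whose mates place
    concordantly (same reference, opposite strands, read arrangement
    consistent, outer distance >= ``min_fragment``) are reported -- discordant
    or part-mapping pairs are dropped entirely.
    """
    if not references:
        raise ValueError("references must be non-empty")
    index = ReferenceIndex(references, k=k)
    out: list[AlignmentRecord] = []
    if mode == "single":
        for read_id, seq, qual in reads:
            placements = _place_single(index, seq, max_mismatches)
            if not placements:
                continue
            mapq = MAPQ_UNIQUE if len(placements) == 1 else MAPQ_AMBIGUOUS
            out.append(_record(read_id, seq, qual, placements[0], mapq))
        return out
    if mode != "paired_no_mixed":
        raise ValueError(f"unknown mode {mode!r}")
    for pair_id, s1, q1, s2, q2 in reads:
        p1 = _place_single(index, s1, max_mismatches)
        p2 = _place_single(index, s2, max_mismatches)
        combos = []
        for a in p1[:50]:
            for b in p2[:50]:
                if a[0] != b[0] or a[2] == b[2]:
                    continue
                left, right = (a, b) if a[1] <= b[1] else (b, a)
                # forward mate must be the leftmost of the pair
                if left[2] != "+" or right[2] != "-":
                    continue
                frag = (right[1] + len(s1 if right is a else s2)) - left[1]
                if frag < max(min_fragment, len(s1)):
                    continue
                combos.append((a, b, frag))
        if not combos:
            continue
        best = min(c[0][3] + c[1][3] for c in combos)
        best_combos = sorted(
            (c for c in combos if c[0][3] + c[1][3] == best),
            key=lambda c: (c[0][0], c[0][1], c[1][1]))
        a, b, frag = best_combos[0]
        mapq = MAPQ_UNIQUE if len(best_combos) == 1 else MAPQ_AMBIGUOUS
        common = dict(is_paired=True, proper_pair=True, fragment_length=frag)
        out.append(_record(pair_id, s1, q1, a, mapq, is_read1=True, **common))
        out.append(_record(pair_id, s2, q2, b, mapq, is_read1=False, **common))
    return out


@dataclass(frozen=True)
class CoverageSummary:
    reference_id: str
    mapped_read_count: int
    reference_length: int
    total_library_reads: int

    @property
    def rpbm(self) -> float:
        """Reads per base-pair per million library reads."""
        return (self.mapped_read_count / self.reference_length
                / (self.total_library_reads / 1e6))


def compute_rpbm(alignments: Sequence[AlignmentRecord], reference_id: str,
                 total_library_reads: int,
                 reference_length: int | None = None) -> CoverageSummary:
    """Coverage summary for one reference; each mapped read counts once."""
    if total_library_reads <= 0:
        raise ValueError("total_library_reads must be positive")
    hits = [a for a in alignments if a.reference_id == reference_id]
    if reference_length is None:
        if not hits:
            raise KeyError(f"no alignments to {reference_id!r} and no "
                           "reference_length given")
        reference_length = max(a.end for a in hits)
    return CoverageSummary(reference_id=reference_id,
                           mapped_read_count=len(hits),
                           reference_length=reference_length,
                           total_library_reads=total_library_reads)


UNORIENTED = "unoriented"


def orient_contig(alignments: Sequence[AlignmentRecord],
                  forward_id: str, reverse_id: str,
                  junctions: dict[str, tuple[int, int]]) -> str:
    """Majority vote over clone-site junction-spanning reads.

    ``junctions`` maps each orientation reference to its two clone-site
    junction positions.  A read votes for an orientation if it covers at
    least one base on each side of either junction.  Ties (including zero
    junction reads) return the ``"unoriented"`` sentinel.
    """
    votes = {forward_id: 0, reverse_id: 0}
    for a in alignments:
        if a.reference_id in votes:
            j1, j2 = junctions[a.reference_id]
            if a.spans(j1) or a.spans(j2):
                votes[a.reference_id] += 1
    if votes[forward_id] > votes[reverse_id]:
        return "forward"
    if votes[reverse_id] > votes[forward_id]:
        return "reverse"
    return UNORIENTED


def contig_in_vector_references(backbone: str, clone_site: int,
                                contig: str, contig_id: str
                                ) -> tuple[dict[str, str], dict[str, tuple[int, int]]]:
    """Both orientations of a contig placed at the vector clone site.

    Returns the two references and their clone-site junction coordinates.
    """
    refs, junctions = {}, {}
    for tag, seq in ((f"{contig_id}|fwd", contig),
                     (f"{contig_id}|rev", reverse_complement(contig))):
        refs[tag] = backbone[:clone_site] + seq + backbone[clone_site:]
        junctions[tag] = (clone_site, clone_site + len(seq))
    return refs, junctions


# --- SAM round-trip -------------------------------------------------------

def write_sam(alignments: Sequence[AlignmentRecord],
              reference_lengths: dict[str, int], path: str | Path) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": rid, "LN": length}
                     for rid, length in sorted(reference_lengths.items())]}
    ref_ids = [sq["SN"] for sq in header["SQ"]]
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_id = ref_ids.index(a.reference_id)
            seg.reference_start = a.start
            seg.mapping_quality = a.mapping_quality
            seg.cigartuples = [(0, len(a.sequence))]
            seg.query_sequence = a.sequence
            seg.query_qualities = pysam.qualitystring_to_array(a.base_qualities)
            flag = 0
            if a.strand == "-":
                flag |= 0x10
            if a.is_paired:
                flag |= 0x1 | (0x40 if a.is_read1 else 0x80)
                if a.proper_pair:
                    flag |= 0x2
            seg.flag = flag
            if a.fragment_length is not None:
                seg.template_length = a.fragment_length
            seg.set_tag("NM", a.n_mismatches)
            out.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            out.append(AlignmentRecord(
                read_id=seg.query_name,
                reference_id=seg.reference_name,
                start=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                n_mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                mapping_quality=seg.mapping_quality,
                sequence=seg.query_sequence or "",
                base_qualities=pysam.qualities_to_qualitystring(
                    seg.query_qualities) if seg.query_qualities is not None else "",
                is_read1=not seg.is_read2,
                is_paired=seg.is_paired,
                proper_pair=seg.is_proper_pair,
                fragment_length=seg.template_length or None,
            ))
    return out
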