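"""Escape-mutant genotyping at protospacer/PAM windows.

After two rounds of selection, surviving plasmids either encode an Acr or
escaped Cas9 some other way.  This module implements the sequencing-based
escape computations:

* per-position base counts at each target-site window, filtered on mapping
  quality (>= 25) and base quality (>= 30);
* the wild-type-site proportion, conservatively computed as the product of
  wild-type base-call fractions over all protospacer/PAM positions, adjusted
  multiplicatively for the frequency of recombination variants that delete a
  site outright;
* the frequency of those recombination variants from junction-spanning reads;
* contig <-> target-site linkage verdicts from long-fragment read pairs, with
  the elimination rules: more than one variant-supporting read kills the
  linked contig, and at shallow linkage (< 10 reads) a single variant read
  suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping_coverage import AlignmentRecord
from .synthetic_library import BASES, VectorMap

DEFAULT_MIN_MAPQ = 25
DEFAULT_MIN_BASEQ = 30
LINKAGE_MIN_MAPQ = 10       # linkage uses "over ten", i.e. strictly greater
LINKAGE_MIN_READS = 10

KEEP, ELIMINATE, UNLINKED = "keep", "eliminate", "unlinked"


@dataclass
class TargetSiteCall:
    """Per-position base counts over one protospacer+PAM window."""

    site_id: str
    window_start: int
    wt_bases: str
    counts: np.ndarray  # shape (window, 4), columns ordered A, C, G, T
    min_mapping_quality: int = DEFAULT_MIN_MAPQ
    min_base_quality: int = DEFAULT_MIN_BASEQ

    @property
    def window_length(self) -> int:
        return len(self.wt_bases)

    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def wt_fractions(self) -> np.ndarray:
        """Fraction of wild-type calls per position; NaN where uncovered."""
        cov = self.coverage().astype(float)
        wt_idx = [BASES.index(b) for b in self.wt_bases]
        wt = self.counts[np.arange(self.window_length), wt_idx].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, wt / cov, np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Per-column counting layout: site, position, ref base, ACGT, wt fraction."""
        fr = self.wt_fractions()
        return pd.DataFrame({
            "site": self.site_id,
            "position": np.arange(self.window_length),
            "ref_base": list(self.wt_bases),
            "A": self.counts[:, 0], "C": self.counts[:, 1],
            "G": self.counts[:, 2], "T": self.counts[:, 3],
            "wt_fraction": fr,
        })


def site_base_frequencies(alignments: Sequence[AlignmentRecord],
                          vector_seq: str, vmap: VectorMap, site_id: str,
                          min_mapping_quality: int = DEFAULT_MIN_MAPQ,
                          min_base_quality: int = DEFAULT_MIN_BASEQ
                          ) -> TargetSiteCall:
    """Count bases at one target-site window from vector-mapped reads.

    Only alignments with mapping quality >= ``min_mapping_quality``
    contribute, and only bases called at quality >= ``min_base_quality``.
    Alignments are ungapped, so column c of the window reads straight off
    each overlapping record.
    """
    start, end = vmap.site_window(site_id)
    wt = vector_seq[start:end]
    counts = np.zeros((end - start, 4), dtype=np.int64)
    for a in alignments:
        if a.mapping_quality < min_mapping_quality:
            continue
        lo, hi = max(a.start, start), min(a.end, end)
        for pos in range(lo, hi):
            base = a.sequence[pos - a.start]
            qual = ord(a.base_qualities[pos - a.start]) - 33
            if qual < min_base_quality or base not in BASES:
                continue
            counts[pos - start, BASES.index(base)] += 1
    return TargetSiteCall(site_id=site_id, window_start=start, wt_bases=wt,
                          counts=counts,
                          min_mapping_quality=min_mapping_quality,
                          min_base_quality=min_base_quality)


@dataclass(frozen=True)
class WtProportion:
    """Wild-type target-site proportion of a library."""

    per_site: dict[str, float]
    combined: float
    recombination_frequency: float
    skipped_positions: dict[str, int]

    @property
    def adjusted(self) -> float:
        """Combined product discounted by the recombination-variant fraction.

        Recombinants read wild-type at the remaining site yet escape Cas9, so
        they inflate the base-call product and are multiplied out.
        """
        return self.combined * (1.0 - self.recombination_frequency)


def wildtype_proportion(calls: Sequence[TargetSiteCall],
                        recombination_frequency: float = 0.0) -> WtProportion:
    """Product of wild-type base-call fractions over all site positions.

    Positions with zero passing coverage are skipped (and counted in
    ``skipped_positions``) rather than zeroing whole libraries.
    """
    if not (0.0 <= recombination_frequency <= 1.0):
        raise ValueError("recombination_frequency must lie in [0, 1]")
    per_site, skipped = {}, {}
    combined = 1.0
    for call in calls:
        fr = call.wt_fractions()
        covered = ~np.isnan(fr)
        prod = float(np.prod(fr[covered])) if covered.any() else float("nan")
        per_site[call.site_id] = prod
        skipped[call.site_id] = int((~covered).sum())
        if covered.any():
            combined *= prod
    return WtProportion(per_site=per_site, combined=combined,
                        recombination_frequency=recombination_frequency,
                        skipped_positions=skipped)


def recombination_frequency(variant_alignments: Sequence[AlignmentRecord],
                            wildtype_alignments: Sequence[AlignmentRecord],
                            variant_junction: int,
                            wildtype_junction: int) -> float | None:
    """Fraction v/(v+w) of reads spanning the recombination junction.

    ``v`` counts reads on the recombinant reference covering >= 1 base on
    each side of the deletion junction; ``w`` counts reads spanning the
    homologous position on the wild-type reference.  Returns ``None`` when
    neither reference has a spanning read.
    """
    v = sum(a.spans(variant_junction) for a in variant_alignments)
    w = sum(a.spans(wildtype_junction) for a in wildtype_alignments)
    if v + w == 0:
        return None
    return v / (v + w)


@dataclass(frozen=True)
class LinkageVerdict:
    contig_id: str
    site_id: str
    n_linked_reads: int
    n_variant_reads: int
    verdict: str
    reason: str


def classify_linkage(n_linked: int, n_variant: int) -> tuple[str, str]:
    """The elimination rules as a pure function of the two counts."""
    if n_linked == 0:
        return UNLINKED, "no reads link this contig to the target site"
    if n_variant > 1:
        return ELIMINATE, ("more than one mapped read supported a "
                           "protospacer/PAM variant")
    if n_linked < LINKAGE_MIN_READS and n_variant >= 1:
        return ELIMINATE, ("fewer than ten linked reads and a read with a "
                           "deviation from the wild-type protospacer/PAM")
    return KEEP, "no disqualifying variant support"


def link_contig_genotype(alignments: Sequence[AlignmentRecord],
                         window: tuple[int, int], wt_bases: str,
                         contig_id: str, site_id: str,
                         orientation: str = "forward",
                         min_mapping_quality: int = LINKAGE_MIN_MAPQ
                         ) -> LinkageVerdict:
    """Link one contig to one target-site genotype.

    ``alignments`` are reads pre-filtered to concordant long-fragment pairs
    mapped on the contig-in-vector reference in the orientation chosen by the
    junction vote; ``window`` is the site's protospacer+PAM interval on that
    reference.  Only alignments with mapping quality strictly greater than
    ``min_mapping_quality`` are considered.  A variant read covers >= 1
    window position with a non-wild-type base call (counted per read).
    """
    if orientation == "unoriented":
        return LinkageVerdict(contig_id, site_id, 0, 0, UNLINKED,
                              "unoriented")
    start, end = window
    n_linked = n_variant = 0
    for a in alignments:
        if a.mapping_quality <= min_mapping_quality:
            continue
        lo, hi = max(a.start, start), min(a.end, end)
        if lo >= hi:
            continue
        n_linked += 1
        if any(a.sequence[p - a.start] != wt_bases[p - start]
               for p in range(lo, hi)):
            n_variant += 1
    verdict, reason = classify_linkage(n_linked, n_variant)
    return LinkageVerdict(contig_id=contig_id, site_id=site_id,
                          n_linked_reads=n_linked, n_variant_reads=n_variant,
                          verdict=verdict, reason=reason)
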