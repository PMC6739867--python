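"""Post-assembly contig triage.

The filter cascade that produces the final putative-antagonist contig set,
applied in the narrated order with every removal recorded:

1. vector decoy removal (>= 99% identity over >= 50% of the contig);
2. coverage floor (RPBM < 2 removed; the threshold sits just above the
   observed coverage maximum of vector-derived contigs, 1.67 RPBM);
3. escape-linked removal (any target site with an *eliminate* linkage verdict);
4. greedy redundancy clustering within library (95% identity over 95% of the
   shorter sequence, best-cluster semantics);
5. cross-contamination screen across libraries (the higher-coverage
   near-identical copy is presumed the source);
6. phage-association annotation from protein homology-hit tables (top-five
   hits in predicted phage; annotation only, no removal).

Pairwise identity uses a k-mer-anchored ungapped diagonal alignment with
X-drop extension; identity = matches / aligned columns, coverage = aligned
columns / length of the relevant sequence.  Sufficient for substitution-level
divergence, which is all these filters must resolve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .escape_genotyping import ELIMINATE, LinkageVerdict
from .synthetic_library import reverse_complement

DEFAULT_ANCHOR_K = 15
XDROP = 30
MATCH_SCORE, MISMATCH_SCORE = 1, -3


@dataclass
class ContigRecord:
    """An assembled insert with its coverage, linkage verdicts and flags."""

    contig_id: str
    sequence: str
    source_library: str = ""
    rpbm: float | None = None
    linkage: dict[str, LinkageVerdict] = field(default_factory=dict)
    flags: list[tuple[str, str]] = field(default_factory=list)  # (stage, reason)

    def flag(self, stage: str, reason: str) -> None:
        self.flags.append((stage, reason))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StageEntry:
    name: str
    input_count: int
    removed: dict[str, str]  # contig_id -> reason
    output_count: int


@dataclass
class FilterLedger:
    """Ordered record of what each stage removed and why."""

    stages: list[StageEntry] = field(default_factory=list)

    def add(self, name: str, input_count: int, removed: dict[str, str]) -> None:
        self.stages.append(StageEntry(name, input_count, dict(removed),
                                      input_count - len(removed)))

    def conserved(self) -> bool:
        ok = all(s.input_count - len(s.removed) == s.output_count
                 for s in self.stages)
        chained = all(self.stages[i].output_count == self.stages[i + 1].input_count
                      for i in range(len(self.stages) - 1))
        ids = [cid for s in self.stages for cid in s.removed]
        return ok and chained and len(ids) == len(set(ids))

    def to_json(self) -> str:
        return json.dumps([{
            "stage": s.name, "input": s.input_count,
            "removed": s.removed, "output": s.output_count,
        } for s in self.stages], indent=2)

    def __str__(self) -> str:
        lines = []
        for s in self.stages:
            lines.append(f"{s.name}: {s.input_count} -> {s.output_count}")
            for cid, why in sorted(s.removed.items()):
                lines.append(f"  - {cid}: {why}")
        return "\n".join(lines)


# --- pairwise identity ----------------------------------------------------

def _best_diagonal_alignment(query: str, subject: str,
                             k: int = DEFAULT_ANCHOR_K
                             ) -> tuple[int, int] | None:
    """Best ungapped alignment of query against subject.

    Anchors shared k-mers, groups them by diagonal, and X-drop-extends the
    densest diagonals.  Returns (matches, aligned_columns) for the best
    span by match count, or None without any anchor.
    """
    if len(query) < k or len(subject) < k:
        return None
    subj_kmers: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        subj_kmers.setdefault(subject[i:i + k], []).append(i)
    diagonals: dict[int, list[int]] = {}
    for i in range(len(query) - k + 1):
        for j in subj_kmers.get(query[i:i + k], []):
            diagonals.setdefault(j - i, []).append(i)
    if not diagonals:
        return None
    best = None
    ranked = sorted(diagonals, key=lambda d: -len(diagonals[d]))[:5]
    for d in ranked:
        qpos = diagonals[d]
        lo, hi = min(qpos), max(qpos) + k  # anchored core, query coords
        matches = sum(query[p] == subject[p + d] for p in range(lo, hi))
        span = hi - lo
        # X-drop extension outward on the same diagonal
        for step, bound in ((-1, -1), (1, len(query))):
            score = drop_max = 0
            p = (lo - 1) if step < 0 else hi
            gained_m = gained_c = best_m = best_c = 0
            while (p != bound) and (0 <= p + d < len(subject)):
                gained_c += 1
                if query[p] == subject[p + d]:
                    gained_m += 1
                    score += MATCH_SCORE
                else:
                    score += MISMATCH_SCORE
                if score > drop_max:
                    drop_max, best_m, best_c = score, gained_m, gained_c
                elif drop_max - score > XDROP:
                    break
                p += step
            matches += best_m
            span += best_c
        if best is None or matches > best[0]:
            best = (matches, span)
    return best


def pairwise_match(query: str, subject: str, k: int = DEFAULT_ANCHOR_K
                   ) -> tuple[float, int]:
    """Best (identity, aligned_columns) over both strands of the query."""
    best_matches, best_span = -1, 0
    for q in (query, reverse_complement(query)):
        hit = _best_diagonal_alignment(q, subject, k=k)
        if hit is not None and hit[0] > best_matches:
            best_matches, best_span = hit
    if best_span == 0:
        return 0.0, 0
    return best_matches / best_span, best_span


def _matches(query: str, subject: str, min_identity: float,
             min_coverage: float, of: str) -> tuple[bool, float]:
    ident, span = pairwise_match(query, subject)
    denom = len(query) if of == "query" else min(len(query), len(subject))
    cov = span / denom if denom else 0.0
    return (ident >= min_identity and cov >= min_coverage), ident


# --- filter stages --------------------------------------------------------

def remove_vector_contigs(contigs: Sequence[ContigRecord],
                          decoys: dict[str, str],
                          min_identity: float = 0.99,
                          min_coverage: float = 0.5
                          ) -> tuple[list[ContigRecord], dict[str, str]]:
    """Drop contigs matching a vector decoy at >= 99% identity over >= 50%."""
    if not decoys:
        raise ValueError("decoys must be non-empty")
    kept, removed = [], {}
    for c in contigs:
        hit = None
        for name in sorted(decoys):
            ok, ident = _matches(c.sequence, decoys[name], min_identity,
                                 min_coverage, of="query")
            if ok:
                hit = (name, ident)
                break
        if hit:
            reason = f"matches decoy {hit[0]} at {hit[1]:.1%} identity"
            c.flag("vector_match", reason)
            removed[c.contig_id] = reason
        else:
            kept.append(c)
    return kept, removed


def coverage_filter(contigs: Sequence[ContigRecord], rpbm_min: float = 2.0
                    ) -> tuple[list[ContigRecord], dict[str, str]]:
    """Strictly-less-than removal: RPBM < threshold removed, == kept."""
    kept, removed = [], {}
    for c in contigs:
        if c.rpbm is None:
            raise ValueError(f"contig {c.contig_id} has no RPBM set")
        if c.rpbm < rpbm_min:
            reason = f"coverage {c.rpbm:.2f} RPBM < {rpbm_min:g}"
            c.flag("low_coverage", reason)
            removed[c.contig_id] = reason
        else:
            kept.append(c)
    return kept, removed


def escape_linked_filter(contigs: Sequence[ContigRecord]
                         ) -> tuple[list[ContigRecord], dict[str, str]]:
    """Drop contigs with an *eliminate* linkage verdict at any target site."""
    kept, removed = [], {}
    for c in contigs:
        bad = [v for v in c.linkage.values() if v.verdict == ELIMINATE]
        if bad:
            reason = (f"linked to escape genotype at site "
                      f"{bad[0].site_id}: {bad[0].reason}")
            c.flag("escape_linked", reason)
            removed[c.contig_id] = reason
        else:
            kept.append(c)
    return kept, removed


def cluster_redundant(contigs: Sequence[ContigRecord],
                      identity: float = 0.95, short_coverage: float = 0.95
                      ) -> tuple[list[ContigRecord], dict[str, str]]:
    """Greedy incremental clustering, longest first, best-cluster assignment.

    Each contig joins the highest-identity existing representative sharing
    >= ``identity`` over >= ``short_coverage`` of the shorter sequence, else
    founds its own cluster.  Cluster representatives are returned; shorter
    members are removed as redundant.
    """
    order = sorted(contigs, key=lambda c: (-len(c), c.contig_id))
    reps: list[ContigRecord] = []
    removed: dict[str, str] = {}
    for c in order:
        best_rep, best_ident = None, identity
        for r in reps:
            ok, ident = _matches(c.sequence, r.sequence, identity,
                                 short_coverage, of="shorter")
            if ok and ident >= best_ident:
                best_rep, best_ident = r, ident
        if best_rep is None:
            reps.append(c)
        else:
            reason = (f"redundant with {best_rep.contig_id} "
                      f"({best_ident:.1%} identity)")
            c.flag("redundant", reason)
            removed[c.contig_id] = reason
    reps.sort(key=lambda c: c.contig_id)
    return reps, removed


def detect_cross_contamination(representatives: Sequence[ContigRecord],
                               all_unfiltered: Sequence[ContigRecord],
                               identity: float = 0.95,
                               short_coverage: float = 0.95
                               ) -> tuple[list[ContigRecord], dict[str, str]]:
    """Screen representatives against the unfiltered set of other libraries.

    A representative matching (95/95 of the shorter) a contig from a
    different library is removed when the other copy has higher coverage
    (ties broken by library name) -- the higher-coverage copy is presumed
    the contamination source.
    """
    kept, removed = [], {}
    for rep in representatives:
        donor = None
        for other in sorted(all_unfiltered, key=lambda c: c.contig_id):
            if other.source_library == rep.source_library:
                continue
            ok, _ = _matches(rep.sequence, other.sequence, identity,
                             short_coverage, of="shorter")
            if not ok:
                continue
            rep_cov = rep.rpbm or 0.0
            oth_cov = other.rpbm or 0.0
            if (oth_cov, rep.source_library) > (rep_cov, other.source_library):
                donor = other
                break
        if donor is None:
            kept.append(rep)
        else:
            reason = (f"cross-contaminant from library "
                      f"{donor.source_library} ({donor.contig_id})")
            rep.flag("cross_contaminant", reason)
            removed[rep.contig_id] = reason
    return kept, removed


# --- homology-hit tables --------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_length: int
    rank: int = 1
    subject_is_phage: bool = False
    contig_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must lie in [0, 100]")


def hits_frame(hits: Iterable[HomologyHit] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        return hits
    return pd.DataFrame([vars(h) for h in hits])


def classify_phage_associated(contig_id: str,
                              hits: Iterable[HomologyHit] | pd.DataFrame,
                              top_n: int = 5) -> bool:
    """True iff any protein of the contig has a top-``top_n`` hit in a
    predicted phage."""
    df = hits_frame(hits)
    if df.empty:
        return False
    sub = df[df["contig_id"] == contig_id]
    return bool(((sub["rank"] <= top_n) & sub["subject_is_phage"]).any())


def filter_homologs(hits: Iterable[HomologyHit] | pd.DataFrame,
                    min_identity: float = 35.0,
                    min_query_coverage: float = 0.75) -> pd.DataFrame:
    """High-confidence homolog set: >= 35% identity covering >= 75% of the
    query."""
    df = hits_frame(hits)
    if df.empty:
        return df
    if (df["query_length"] <= 0).any():
        raise ValueError("query_length must be positive")
    cov = df["alignment_length"] / df["query_length"]
    return df[(df["percent_identity"] >= min_identity)
              & (cov >= min_query_coverage)].reset_index(drop=True)


# --- the cascade ----------------------------------------------------------

def run_filter_pipeline(contigs: Sequence[ContigRecord],
                        decoys: dict[str, str],
                        hits: Iterable[HomologyHit] | pd.DataFrame | None = None,
                        rpbm_min: float = 2.0,
                        cluster_identity: float = 0.95,
                        short_coverage: float = 0.95,
                        whitelist: Sequence[str] = (),
                        ) -> tuple[list[ContigRecord], FilterLedger]:
    """Apply the full triage cascade and record a :class:`FilterLedger`.

    ``whitelist`` names contigs exempt from escape-linked removal (the
    empirically-validated-antagonist escape hatch); phage association is
    annotated on the survivors but removes nothing.
    """
    ledger = FilterLedger()
    current = sorted(contigs, key=lambda c: c.contig_id)
    all_unfiltered = list(contigs)

    kept, removed = remove_vector_contigs(current, decoys)
    ledger.add("remove_vector_contigs", len(current), removed)
    current = kept

    kept, removed = coverage_filter(current, rpbm_min=rpbm_min)
    ledger.add("coverage_filter", len(current), removed)
    current = kept

    shielded = [c for c in current if c.contig_id in set(whitelist)]
    exposed = [c for c in current if c.contig_id not in set(whitelist)]
    kept, removed = escape_linked_filter(exposed)
    ledger.add("escape_linked_filter", len(current), removed)
    current = sorted(kept + shielded, key=lambda c: c.contig_id)

    reps: list[ContigRecord] = []
    removed = {}
    for lib in sorted({c.source_library for c in current}):
        lib_reps, lib_removed = cluster_redundant(
            [c for c in current if c.source_library == lib],
            identity=cluster_identity, short_coverage=short_coverage)
        reps.extend(lib_reps)
        removed.update(lib_removed)
    ledger.add("cluster_redundant", len(current), removed)
    current = sorted(reps, key=lambda c: c.contig_id)

    kept, removed = detect_cross_contamination(
        current, all_unfiltered, identity=cluster_identity,
        short_coverage=short_coverage)
    ledger.add("detect_cross_contamination", len(current), removed)
    current = kept

    if hits is not None:
        for c in current:
            if classify_phage_associated(c.contig_id, hits):
                c.flag("phage_associated", "top-five protein hit in a "
                       "predicted phage")
    ledger.add("classify_phage_associated", len(current), {})
    return current, ledger
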