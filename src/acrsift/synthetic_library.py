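"""Synthetic clone libraries, vector maps, and paired-end read emission.

The selection this package models screens small-insert metagenomic libraries
cloned into a kanamycin-marked plasmid vector.  The vector carries two SpyCas9
target sites (protospacer + NGG PAM) inside the resistance marker, 514 bp and
365 bp from the clone site, so that a plasmid survives Cas9 induction only if
it encodes an anti-CRISPR (Acr), its host has lost Cas9 function, or its
target sites have mutated or recombined away.

Everything here is deterministic for a fixed seed and carries an explicit
truth table so that every downstream stage (alignment, coverage, genotyping,
filtering) is testable without any external data.

Coordinates are 0-based, half-open throughout; FASTQ/SAM emission uses the
standard file conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# quality convention: correct bases Q37, substituted bases Q20 (Phred+33)
QUAL_CORRECT = chr(37 + 33)  # 'F'
QUAL_ERROR = chr(20 + 33)    # '5'

# site-state kinds
WILD_TYPE = "wild_type"
POINT_MUTANT = "point_mutant"
DELETED = "deleted_by_recombination"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class VectorMap:
    """Layout of the cloning vector around the clone site and target sites.

    Site offsets measure the distance from the clone-site boundary to the
    nearest base of the protospacer.  Both protospacer+PAM windows must lie
    inside the resistance-marker interval and clear of the clone site.
    """

    backbone_length: int = 2500
    clone_site: int = 100
    site_a_offset: int = 514
    site_b_offset: int = 365
    protospacer_length: int = 20
    pam_length: int = 3
    marker_interval: tuple[int, int] = (400, 1216)

    def __post_init__(self) -> None:
        if not (0 <= self.clone_site <= self.backbone_length):
            raise ValueError("clone_site outside backbone")
        lo, hi = self.marker_interval
        for sid in ("A", "B"):
            s, e = self.site_window(sid)
            if not (lo <= s and e <= hi):
                raise ValueError(f"target site {sid} window outside marker_interval")
            if s < self.clone_site < e:
                raise ValueError(f"target site {sid} overlaps the clone site")

    @property
    def window_length(self) -> int:
        return self.protospacer_length + self.pam_length

    def site_offset(self, site_id: str) -> int:
        try:
            return {"A": self.site_a_offset, "B": self.site_b_offset}[site_id]
        except KeyError:
            raise KeyError(f"unknown target site {site_id!r}") from None

    def site_window(self, site_id: str, insert_length: int = 0) -> tuple[int, int]:
        """Half-open window of protospacer+PAM, optionally shifted by an insert.

        With ``insert_length`` > 0 the coordinates refer to a plasmid in which
        an insert of that length occupies the clone site.
        """
        start = self.clone_site + insert_length + self.site_offset(site_id)
        return start, start + self.window_length


def vector_sequence(vmap: VectorMap, seed: int = 0) -> str:
    """Deterministic synthetic backbone with NGG PAMs at both target sites."""
    rng = np.random.default_rng([seed, 0xACF])
    seq = list(random_dna(vmap.backbone_length, rng))
    for sid in ("A", "B"):
        s, _ = vmap.site_window(sid)
        pam = s + vmap.protospacer_length
        seq[pam:pam + vmap.pam_length] = list("AGG"[: vmap.pam_length])
    return "".join(seq)


@dataclass(frozen=True)
class SiteState:
    """State of one protospacer/PAM window in a clone's plasmid."""

    kind: str
    position: int | None = None  # 0-based within the protospacer+PAM window
    base: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (WILD_TYPE, POINT_MUTANT, DELETED):
            raise ValueError(f"unknown site state {self.kind!r}")
        if self.kind == POINT_MUTANT and (self.position is None or self.base is None):
            raise ValueError("point_mutant requires position and base")


@dataclass(frozen=True)
class CloneGenotype:
    insert_id: str
    insert_sequence: str
    has_acr: bool
    site_a_state: SiteState
    site_b_state: SiteState
    cas9_lof: bool

    @property
    def n_intact_wild_type_sites(self) -> int:
        return sum(s.kind == WILD_TYPE for s in (self.site_a_state, self.site_b_state))


@dataclass(frozen=True)
class LibrarySpec:
    """Composition of a synthetic clone library.

    Rates follow the study conditions: libraries of order 10^6 unique clones
    with ~2 kb mean inserts, Cas9 loss-of-function escape at 10^-4..10^-5, and
    a tiny Acr-bearing fraction.
    """

    n_unique_clones: int
    acr_frequency: float = 1e-6
    lof_rate: float = 1e-4
    site_mutation_rate: float = 1e-5
    recombination_rate: float = 0.0
    insert_length_mean: float = 2000.0
    insert_length_sd: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unique_clones < 1:
            raise ValueError("n_unique_clones must be >= 1")
        for name in ("acr_frequency", "lof_rate", "site_mutation_rate",
                     "recombination_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.insert_length_mean <= 0:
            raise ValueError("insert_length_mean must be positive")


# integer codes for vectorized site states
_WT, _PM, _DEL = 0, 1, 2
_STATE_NAMES = {_WT: WILD_TYPE, _PM: POINT_MUTANT, _DEL: DELETED}

# in-frame deletion length for recombination variants: protospacer+PAM (23 bp)
# rounded up to a codon multiple
def recombination_deletion_length(vmap: VectorMap) -> int:
    w = vmap.window_length
    return w + (-w) % 3


@dataclass
class LibraryModel:
    """A realized clone library: per-clone genotypes and frequencies.

    Insert sequences are materialized lazily (deterministically from the seed
    and clone index) so that million-clone libraries stay cheap to build.
    """

    spec: LibrarySpec
    vmap: VectorMap
    frequencies: np.ndarray
    has_acr: np.ndarray
    cas9_lof: np.ndarray
    site_state_code: np.ndarray      # (n, 2) int, columns = site A, site B
    mutant_position: np.ndarray      # (n, 2) int, -1 where not a point mutant
    mutant_base: np.ndarray          # (n, 2) int index into BASES, -1 unused
    insert_length: np.ndarray
    backbone: str = ""
    _plasmid_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.backbone == "":
            self.backbone = vector_sequence(self.vmap, self.spec.seed)

    @property
    def n_clones(self) -> int:
        return len(self.frequencies)

    def insert_sequence(self, i: int) -> str:
        rng = np.random.default_rng([self.spec.seed, 0x1A5, int(i)])
        return random_dna(int(self.insert_length[i]), rng)

    def clone(self, i: int) -> CloneGenotype:
        states = []
        for col in (0, 1):
            code = int(self.site_state_code[i, col])
            if code == _PM:
                states.append(SiteState(POINT_MUTANT,
                                        int(self.mutant_position[i, col]),
                                        BASES[int(self.mutant_base[i, col])]))
            else:
                states.append(SiteState(_STATE_NAMES[code]))
        return CloneGenotype(
            insert_id=f"clone_{i:06d}",
            insert_sequence=self.insert_sequence(i),
            has_acr=bool(self.has_acr[i]),
            site_a_state=states[0],
            site_b_state=states[1],
            cas9_lof=bool(self.cas9_lof[i]),
        )

    def plasmid_sequence(self, i: int) -> str:
        """Full plasmid of clone i: backbone with insert, site mutations applied.

        The plasmid is treated as a linear sequence (fragments never span the
        notional origin); the clone-site junctions sit at ``clone_site`` and
        ``clone_site + insert_length``.
        """
        if i in self._plasmid_cache:
            return self._plasmid_cache[i]
        cs = self.vmap.clone_site
        ins = self.insert_sequence(i)
        seq = list(self.backbone[:cs] + ins + self.backbone[cs:])
        ilen = len(ins)
        # apply point mutations, then the site-B recombination deletion
        for col, sid in ((0, "A"), (1, "B")):
            if self.site_state_code[i, col] == _PM:
                s, _ = self.vmap.site_window(sid, insert_length=ilen)
                seq[s + int(self.mutant_position[i, col])] = \
                    BASES[int(self.mutant_base[i, col])]
        for col, sid in ((0, "A"), (1, "B")):
            if self.site_state_code[i, col] == _DEL:
                s, _ = self.vmap.site_window(sid, insert_length=ilen)
                del seq[s:s + recombination_deletion_length(self.vmap)]
        out = "".join(seq)
        if len(self._plasmid_cache) < 4096:
            self._plasmid_cache[i] = out
        return out

    def survival_classes(self) -> pd.DataFrame:
        """Aggregate clones into (has_acr, cas9_lof, n intact wt sites) classes.

        Returns a frame with one row per occupied class and its total
        frequency -- the input to the closed-form selection propagation.
        """
        n_wt = (self.site_state_code == _WT).sum(axis=1)
        df = pd.DataFrame({
            "has_acr": self.has_acr,
            "cas9_lof": self.cas9_lof,
            "n_wild_type_sites": n_wt,
            "frequency": self.frequencies,
        })
        out = (df.groupby(["has_acr", "cas9_lof", "n_wild_type_sites"],
                          as_index=False)["frequency"].sum())
        return out


def build_library(spec: LibrarySpec, vmap: VectorMap | None = None) -> LibraryModel:
    """Realize a clone library from a :class:`LibrarySpec`.

    Each clone independently draws Acr carriage, host Cas9 loss of function,
    a site-B recombination deletion, and per-site point mutants (uniform over
    the protospacer+PAM positions and the three alternative bases).  A
    recombined site is never additionally point-mutated.  Clone frequencies
    are uniform.
    """
    vmap = vmap or VectorMap()
    n = spec.n_unique_clones
    rng = np.random.default_rng(spec.seed)

    has_acr = rng.random(n) < spec.acr_frequency
    cas9_lof = rng.random(n) < spec.lof_rate
    recomb = rng.random(n) < spec.recombination_rate  # deletes site B only

    codes = np.zeros((n, 2), dtype=np.int8)
    pos = np.full((n, 2), -1, dtype=np.int32)
    alt = np.full((n, 2), -1, dtype=np.int8)
    codes[recomb, 1] = _DEL
    for col in (0, 1):
        pm = (rng.random(n) < spec.site_mutation_rate) & (codes[:, col] == _WT)
        codes[pm, col] = _PM
        k = int(pm.sum())
        if k:
            pos[pm, col] = rng.integers(0, vmap.window_length, size=k)
            # draw one of the three non-reference bases; resolved lazily
            # against the backbone so store an offset 1..3
            alt[pm, col] = rng.integers(1, 4, size=k)

    lengths = np.maximum(
        np.rint(rng.normal(spec.insert_length_mean, spec.insert_length_sd, size=n)),
        vmap.window_length * 3,
    ).astype(np.int64)

    model = LibraryModel(
        spec=spec, vmap=vmap,
        frequencies=np.full(n, 1.0 / n),
        has_acr=has_acr, cas9_lof=cas9_lof,
        site_state_code=codes, mutant_position=pos, mutant_base=alt,
        insert_length=lengths,
    )
    # resolve alternative-base offsets against the wild-type backbone base
    for col, sid in ((0, "A"), (1, "B")):
        s, _ = vmap.site_window(sid)
        idx = np.flatnonzero(codes[:, col] == _PM)
        for i in idx:
            wt = model.backbone[s + int(pos[i, col])]
            alt_bases = [b for b in BASES if b != wt]
            model.mutant_base[i, col] = BASES.index(alt_bases[int(alt[i, col]) - 1])
    return model


@dataclass(frozen=True)
class ReadSpec:
    """Paired-end sequencing parameters (93 bp usable read length by default)."""

    n_pairs: int
    read_length: int = 93
    insert_size_mean: float = 550.0
    insert_size_sd: float = 100.0
    base_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_size_mean < self.read_length:
            raise ValueError("insert_size_mean must be >= read_length")
        if not (0.0 <= self.base_error_rate < 1.0):
            raise ValueError("base_error_rate must lie in [0, 1)")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")


@dataclass
class PairedReads:
    """In-memory paired FASTQ plus the generating truth table.

    ``truth`` columns: pair_id, clone_id, start, end, strand -- the sampled
    fragment interval on the source clone's full plasmid sequence.  Strand is
    the strand of read 1.
    """

    pairs: list[tuple[str, str, str, str, str]]  # (id, seq1, qual1, seq2, qual2)
    truth: pd.DataFrame

    def __iter__(self) -> Iterator[tuple[str, str, str, str, str]]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def write_fastq(self, path_1: str | Path, path_2: str | Path) -> None:
        with open(path_1, "w") as f1, open(path_2, "w") as f2:
            for pid, s1, q1, s2, q2 in self.pairs:
                f1.write(f"@{pid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{pid}/2\n{s2}\n+\n{q2}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, str]:
    if rate == 0.0:
        return seq, QUAL_CORRECT * len(seq)
    err = rng.random(len(seq)) < rate
    if not err.any():
        return seq, QUAL_CORRECT * len(seq)
    s = list(seq)
    q = [QUAL_CORRECT] * len(seq)
    for j in np.flatnonzero(err):
        s[j] = BASES[(BASES.index(s[j]) + int(rng.integers(1, 4))) % 4]
        q[j] = QUAL_ERROR
    return "".join(s), "".join(q)


def emit_reads(model: LibraryModel, rspec: ReadSpec) -> PairedReads:
    """Sample paired-end reads from a library.

    Each pair samples a clone proportionally to its frequency, a fragment of
    truncated-normal length uniformly positioned on the clone's linear plasmid
    sequence, and independent per-base substitution errors.  Read 1 comes from
    the fragment's 5' end on the recorded strand, read 2 is the reverse
    complement of the 3' end.
    """
    if model.n_clones == 0:
        raise ValueError("empty library model")
    rng = np.random.default_rng(rspec.seed)
    n = rspec.n_pairs
    clone_idx = rng.choice(model.n_clones, size=n, p=model.frequencies)
    rows = []
    pairs = []
    for p in range(n):
        i = int(clone_idx[p])
        plasmid = model.plasmid_sequence(i)
        L = len(plasmid)
        frag = int(np.clip(np.rint(rng.normal(rspec.insert_size_mean,
                                              rspec.insert_size_sd)),
                           rspec.read_length, L))
        start = int(rng.integers(0, L - frag + 1))
        end = start + frag
        strand = "+" if rng.random() < 0.5 else "-"
        fwd = plasmid[start:end]
        if strand == "-":
            fwd = reverse_complement(fwd)
        r1 = fwd[: rspec.read_length]
        r2 = reverse_complement(fwd[-rspec.read_length:])
        s1, q1 = _apply_errors(r1, rng, rspec.base_error_rate)
        s2, q2 = _apply_errors(r2, rng, rspec.base_error_rate)
        pid = f"pair_{p:07d}"
        pairs.append((pid, s1, q1, s2, q2))
        rows.append((pid, f"clone_{i:06d}", start, end, strand))
    truth = pd.DataFrame(rows, columns=["pair_id", "clone_id", "start", "end",
                                        "strand"])
    return PairedReads(pairs=pairs, truth=truth)


def write_references(model: LibraryModel, out_dir: str | Path,
                     max_clones: int | None = None) -> Path:
    """Write the vector backbone and per-clone plasmid FASTA references."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "references.fasta"
    n = model.n_clones if max_clones is None else min(max_clones, model.n_clones)
    with open(path, "w") as fh:
        fh.write(f">vector\n{model.backbone}\n")
        for i in range(n):
            fh.write(f">clone_{i:06d}\n{model.plasmid_sequence(i)}\n")
    return path
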