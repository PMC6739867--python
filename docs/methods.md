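# Methods

## The selection model

One induction round is modeled as independent survival per cell. A clone's
survival probability is `acr_protection` if it carries an Acr (default 1.0
-- the data motivating the default show near-complete protection, and the
parameter stays configurable because the true efficacy is not pinned down),
1 if its host Cas9 is loss-of-function, and otherwise
`lambda + (1 - lambda) mu^k`, where `lambda` (default 1e-4, the empirical
per-transformant loss-of-function escape rate, observed range 1e-4..1e-5)
is the probability the host's Cas9 breaks and `mu` (default 0) the per-site,
per-round probability that an intact wild-type target site escapes
cleavage. Sites that are already point-mutant or deleted by recombination
contribute a factor of 1: they carry no remaining cleavage risk.

Escape variation is primarily *standing*: the library generator realizes
point mutants and recombinants at construction time, and `mu` exists as an
additional per-round arising knob that defaults to zero. Survival events
are independent across clones and rounds; there is no clustering of
loss-of-function mutants, no fitness cost to Acr expression, and no
plate-count noise beyond binomial sampling.

`propagate_expected` applies the exact replicator update
`f' = f s / sum(f s)`; the normalizer is the round's Kan^R proportion
(fraction of cells retaining the plasmid) and its reciprocal the fold
reduction. `propagate_monte_carlo` is the stochastic twin: binomial
survivor draws per class, renormalization, and deterministic
largest-remainder regrowth to `n_cells` between rounds. Deterministic
regrowth (rather than multinomial resampling) makes selection the only
noise source, so the no-selection limit preserves frequencies exactly and
the initial one-in-N clone is present in every replicate -- the regime the
closed-form comparison tests require. Both propagators raise a
library-extinct error carrying the iteration index when no class survives.

The detectability bound scans power-of-ten library sizes N, placing a
single Acr clone at 1/N, and returns the largest N whose final Acr
frequency exceeds the majority threshold after the configured iterations.
The scan propagates in the *rare-clone limit*, `f' = f s_acr / (f s_acr +
s_bg)`, neglecting the depletion of the background by the Acr clone
itself. At the boundary sizes this bound cares about the exact update
differs only by O(f0) terms, but those terms fall exactly on the majority
threshold (a 1-in-1e8 clone lands at frequency 0.5 + 2.5e-9 under the
exact update); the rare-clone limit keeps the bound insensitive to that
knife edge and reproduces the derivation behind the 1e7 figure. The full
propagator remains exact.

## The synthetic data generator

The generator emulates a small-insert functional metagenomic library in a
kanamycin-marked vector. The synthetic backbone is 2,500 bp of seeded
random DNA with two SpyCas9 target sites (20 nt protospacer + NGG PAM; the
protospacer length is an assumption, standard for SpyCas9, and
configurable) placed 514 bp and 365 bp downstream of the clone site inside
the resistance-marker interval. Offsets measure clone-site boundary to the
nearest protospacer base; coordinates are 0-based half-open throughout,
with FASTQ/SAM emitted in their usual conventions.

Defaults follow the study conditions: libraries of order 1e6 unique clones
(the real libraries held 1.3-3.9e6), ~2 kb mean inserts (sd 300 bp),
Acr frequency ~1e-6, loss-of-function rate 1e-4, per-site point-mutation
rate 1e-5. Point mutants are uniform over the 23 protospacer+PAM positions
and the 3 alternative bases. Recombination variants cleanly delete a 24 bp
window at site B (protospacer+PAM rounded up to a codon multiple, keeping
the marker in frame, matching the observed recombinants that removed the
site without a frameshift); at most one site per clone is deleted. Clone
frequencies are uniform; insert sequences are materialized lazily and
deterministically from (seed, clone index) so million-clone libraries stay
cheap.

Read emission samples a clone per pair proportionally to frequency, a
fragment of rounded-normal length (default mean 550 bp, sd 100 bp,
truncated to [read length, plasmid length]) uniform on the clone's linear
plasmid, and independent per-base substitution errors. Reads are 93 bp
(the usable read length of the original data). Base qualities follow a
deliberate two-level convention -- Q37 for correct bases, Q20 for
substituted ones -- so the genotyping base-quality filter (Q30) is
exercisable with known truth. The generator does not model
sequencing-chemistry realism (no quality decay, adapters, duplicates,
indels, chimeras) or assembly, and plasmids are linear rather than
circular (fragments never span the notional origin). Passing tests
therefore demonstrate correctness of the *analysis arithmetic* under clean
substitution-only noise, not robustness to real-library artifacts.

## Alignment and coverage

The built-in placer is intentionally minimal: exact 21-mer seeds at the
read's two ends, ungapped extension, at most 3 mismatches by default.
Unique best placements get mapping quality 60; ties get 0 and are reported
at the lexicographically smallest reference/position. This binary quality
model is sufficient because every downstream threshold (MQ > 10 for
linkage, MQ >= 25 for genotyping) only separates unique from ambiguous
placements. Paired `no_mixed` mode keeps only concordant pairs (same
reference, opposite strands, forward mate leftmost) with outer distance --
the "insert size" -- at or above the minimum (515 bp for linkage, the
smallest fragment that can bridge the nearer target site to the clone
site). Real alignments can be imported from SAM instead; all downstream
stages consume the same record type.

RPBM (reads per base-pair per million library reads) is
`mapped_reads / reference_length / (total_reads / 1e6)`. **It counts
mapped reads, not read-bases**, taking "reads per base-pair" literally;
each mate counts once.

Contig orientation inside the vector is a majority vote of reads spanning
(>= 1 base each side) either clone-site junction of the forward versus the
reverse contig-in-vector reference; ties return an `unoriented` sentinel
rather than a guess, and unoriented contigs are treated as unlinked.

## Escape genotyping

Base counts at each target-site column require mapping quality >= 25 and
base quality >= 30. The wild-type-site proportion is the product of
wild-type call fractions over all protospacer/PAM positions; the combined
statistic multiplies over both sites' 46 positions (a plasmid is wild-type
only if both sites are), with per-site products also reported. Columns
with zero passing coverage are skipped and flagged -- treating them as
zero would annihilate entire libraries on a single coverage gap. The
recombinant fraction is v/(v+w), junction-spanning reads on the
recombinant reference versus reads spanning the homologous window on the
wild-type reference, and discounts the combined product multiplicatively
(`adjusted = combined * (1 - recombination_frequency)`): recombinants read
wild-type at their remaining site yet escape, so they inflate the product.

Linkage verdicts use reads from concordant pairs (fragment >= 515 bp,
mapping quality strictly > 10, both mates required to pass) in the
orientation chosen by the junction vote. A variant read covers at least
one window position with a non-wild-type call and counts once regardless
of how many positions mismatch. A contig is eliminated if more than one
read supports a variant, or if fewer than ten reads link the site and even
one carries a deviation. Verdicts are kept per site; the filter stage
removes a contig if any site's verdict is eliminate.

## Contig triage

Stages run in the narrated order -- vector decoys (>= 99% identity over
>= 50% of the contig; the 50% coverage floor is this package's documented
default), coverage floor (RPBM < 2 removed, exactly 2 kept; the threshold
sits just above the 1.67 RPBM maximum observed for vector-derived
contigs), escape-linked removal, greedy redundancy clustering within
library (longest-first; a contig joins the highest-identity representative
sharing >= 95% identity over >= 95% of the shorter sequence), a
cross-contamination screen against the unfiltered contigs of other
libraries (the higher-coverage copy is presumed the source; ties break by
library name), and phage-association annotation (any protein with a
top-five hit in a predicted phage flags the contig; annotation only).
An explicit whitelist exempts named contigs from escape-linked removal,
modeling the empirically-validated-antagonist exception as an operator
decision rather than an automatic rule. Every removal lands in an ordered
ledger whose stage counts must chain (`input - removed = output`, disjoint
removal sets), and the pipeline's output set is invariant under input
permutation (ties break on contig id).

Pairwise identity is a k-mer-anchored (k=15) ungapped diagonal alignment:
anchors are grouped by diagonal, the densest diagonals are extended
outward with an X-drop rule (match +1, mismatch -3, drop 30), and identity
is matches over aligned columns on the best diagonal, both strands tried.
This resolves substitution-level divergence -- all these filters need --
and deliberately does not model gaps. Homology-hit filtering (>= 35%
identity covering >= 75% of the query) and phage classification consume
external hit tables with named columns; homology search and phage
prediction themselves are out of scope.

## Statistics

The enrichment test is Pearson's chi-squared on a 2x2 table, df=1, no
continuity correction, via the closed form `N(ad-bc)^2 /
((a+b)(c+d)(a+c)(b+d))`. The genus table is built with non-overlapping
rows (recovered genera versus the *remaining* reference genera), since
recovered genera are members of the reference set; a zero marginal is an
error. Protection assays summarize log10(Kan^R/total cfu) per construct
and condition; zero Kan^R counts receive a flagged 0.5-cfu pseudocount
before the log. Comparisons are two-sided equal-variance Student's
t-tests by default (Welch optional) and must be named explicitly -- both
induced-versus-uninduced and construct-versus-empty-vector framings are
supported because the source framings differ. Bonferroni correction
multiplies by the family size and caps at 1. T7E1 indel quantification
uses `100 (1 - sqrt(1 - fraction_cleaved))`; the square root is the
standard heteroduplex correction, and the literal multiply-by-0.5 reading
(which assigns 50% indels to an uncut lane) is available behind a flag
purely for transparency.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale as the package's
own choice of problem size: Monte-Carlo selection uses 1e6-cell
populations over 20 seeds (enough for the 3-standard-error agreement
checks against the closed form), library-composition checks use 200 seeds
of 1e6-clone libraries, and read-level parameter-recovery simulations use
hundreds of clones and ~1e4 read pairs. Library frequencies sum to 1
within 1e-12; identical seeds give byte-identical FASTQ; all scans and
tie-breaks are deterministic.

## Known limitations

Assembly is out of scope: contigs enter the triage as given sequences.
The aligner is ungapped and exact-seeded, so indel-bearing or
heavily-errored reads are simply dropped rather than soft-clipped. The
wild-type-site product is a conservative per-column statistic, not a
genotype likelihood, and slightly overestimates the wild-type fraction
when multiple mutations co-occur on one plasmid. The selection model
ignores growth-rate differences, so enrichment factors reflect survival
only.
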