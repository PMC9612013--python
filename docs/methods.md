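# Methods

This note records the models, algorithms, parameter choices, and limitations
behind plastokit, in the order the pipeline runs them.

## Quadripartite structure detection

**Model.** A plastome is treated as a circular string containing exactly one
pair of long inverted repeats (IR1, IR2 = revcomp(IR1)) separating two
single-copy arcs; the longer arc is the LSC by definition, ties broken by the
smaller start coordinate. Genomes without a qualifying repeat, or with extra
large repeats unrelated to the top pair, raise an explicit error instead of
guessing.

**Algorithm.** Exact k-mer matches (k = 15) between the doubled sequence and
its reverse complement seed candidate pairs. Seeds sharing an anti-diagonal
(position *x* pairing with *c − x*) are merged, truncated at the palindrome
centre so the two arcs stay disjoint, and greedily extended one base at a
time on either side while the running mismatch count stays within
`floor(max_mismatch_frac · length)`; terminal mismatches are trimmed, so
reported pairs are maximal and not extendable within the budget. Coordinates
are folded back to the circle and pairs deduplicated; order is length
descending, then copy1 start. An O(n²) anti-diagonal scan kept in the test
suite serves as the independent oracle on sequences ≤ 5 kb.

**Parameters.** `min_len` defaults to 1000 bp (real plastome IRs are tens of
kb; toy tests override to 50–100). `max_mismatch_frac` defaults to 0.01 for
real assemblies, which carry polishing errors; synthetic genomes plant exact
copies, so tests and the acceptance script detect with a budget of 0 — the
value matched to how the data are generated, not to the detector.

**Canonical form.** For alignment, a genome is rotated to start at LSC
position 1 in the order LSC→IR1→SSC→IR2. Since a circular molecule has no
intrinsic orientation, the lexicographically smaller of the two candidate
strings (as-given vs reverse-complemented, each rotated to its LSC start) is
chosen; this makes canonicalisation idempotent and invariant under arbitrary
rotation and orientation. IR labels are positional: whichever copy follows
the LSC is IR1.

## Synthetic data

The generators define the study conditions for all tests.

- **Plastome** (`PlastomeSpec`): i.i.d. bases at a given GC (default 0.385,
  plastid-like), laid out LSC+IR1+SSC+revcomp(IR1). Defaults are maize-scale
  (82 kb LSC, 12.5 kb SSC, 22.75 kb IRs ≈ 140 kb total); tests use 4.6–10 kb
  versions with the same shape. Two constraints keep the planted partition
  the unique correct answer: single-copy regions are rejection-resampled
  until they contain no spurious inverted repeat of IR length, and the four
  bases flanking the planted pair are redrawn so the repeat is not extendable
  by chance (otherwise a correct maximal-repeat detector would, with
  probability ~1/4 per boundary, legitimately report a longer pair than the
  one planted).
- **Isoforms**: the non-canonical isoform is the canonical sequence with the
  SSC reverse-complemented in place — an involution, equal length, differing
  exactly on the SSC interval.
- **Reads** (`ReadSimParams`): each read draws its source isoform
  (probability `mixture_ratio`, default 0.5 per the flip-flop equilibrium), a
  uniform circular start (sampled from the doubled sequence; reads never
  exceed one genome length), a random strand, and a log-normal length
  (defaults 12 kb ± 8 kb, CLR-like) truncated to [200 bp, genome length].
  Errors are per-base substitutions/insertions/deletions (defaults
  0.03/0.06/0.03, insertion-heavy like CLR chemistry); FASTQ qualities are a
  constant Phred 20 and unused downstream. A truth record (read, isoform,
  start, strand, length) is emitted per read.
- **Populations** (`PopulationSpec`): the ancestor evolves down a rooted
  newick tree under single-site Jukes–Cantor with Poisson(branch ×
  rate × length) substitution counts; indels are Poisson gap events with
  geometric lengths, split evenly between insertions and deletions. The
  simulation tracks a global column order, so the emitted alignment is the
  *true* alignment with the ancestor coordinate per column; `variant_truth`
  lists every ancestral site hit by a substitution with realised per-leaf
  alleles and a `polymorphic` flag computed from the leaves themselves (so
  back-mutations and multiple hits are accounted for exactly).

What the generator does **not** emulate: CLR-specific error profiles,
chimeric or quality-varying reads, coverage biases, context-dependent
substitution (GTR/rate heterogeneity), or selection. Passing tests therefore
demonstrate algorithmic correctness under clean, well-specified conditions —
not robustness to every artefact of real sequencing runs.

## Isoform phasing

**Mapping contract.** Reads are mapped against the four region sequences of
the canonicalised reference, both strands, by exact k-mer seeding (k = 15)
and diagonal-consistent chaining (drift allowance 20 + 0.2·gap, max gap
800 bp). Chain ends within 60 bp of a region boundary are snapped to it, and
candidate full-region hits are re-placed exactly with edlib semi-global
alignment; identities come from edlib edit distances. Hits need identity
≥ 0.85 (the package's re-expression of an aligner-specific mapping-quality
gate) and at least 2k aligned bases (chance 15-mer matches carry no placement
signal). Read-overlap conflicts are resolved by most matched bases
(identity × length), then identity, then a fixed label/strand order so the
inherent IR1(+)/IR2(−) ambiguity of an IR-internal segment resolves
deterministically — the choice is immaterial to phasing, which only compares
the orientations of the single-copy flanks.

**Calling.** A read is *spanning* iff some IR region is fully covered by one
hit with single-copy hits on both sides. The call requires both anchors to
reach `anchor_min` (default 500 bp — comfortably above boundary alignment
slop; there is no canonical literature value) into their regions: same flank
orientations ⇒ canonical, opposite ⇒ non-canonical. Reads spanning both IRs
produce two comparisons that must agree. Everything else is unclassified —
never an exception — and unclassified reads go to a third read-set file so
the two conformation sets stay mutually exclusive.

**Ratio.** With k non-canonical among n classified spanning reads, the
estimate is k/n with a Wilson score 95% interval
(statsmodels `proportion_confint`) and an exact two-sided binomial test
against p₀ = 0.5 (scipy `binomtest`, summing outcome probabilities no larger
than the observed outcome's). Zero classified reads is an explicit
undefined-ratio error.

**Depth check.** On the collapsed (single-IR) representation, both IR copies
contribute depth to one repeat unit, so IR depth ÷ single-copy depth ≈ 2;
the package computes this from mapped segment hits and the test suite checks
it lands in [1.7, 2.3] at ≥ 20× coverage (placement noise at desk-scale
coverage dominates the deviation from 2).

## Alignment variants

Gap-containing columns are never SNVs; they belong to indel events. This
keeps the two classes disjoint, matching the convention of counting SNVs and
indels separately. An indel *event* is a maximal run of adjacent columns
sharing an identical non-trivial gap pattern; since whether published indel
tallies count events or columns is usually ambiguous, both numbers are
reported (`n_events` and `n_columns`). N is missing data: it is excluded
from allele counts and a column whose only variation involves N is
invariant. `min_minor_count` defaults to 1 — no low-frequency filtering, so
positions where a single individual differs still count. All reported
positions are 1-based; VCF output is 1-based with REF checked against the
reference sequence; BED is 0-based half-open.

The coordinate map is a cumulative-sum index over the reference row's
non-gap columns; lift-over is exact and round-trips on every non-gap column.
Marker lists are single-column TSVs of reference positions; SNVs on
reference-gap columns cannot be compared and are counted separately rather
than dropped silently.

## Phylogeny

p-distances use pairwise deletion of gaps and N (a pair with no comparable
columns is an error naming the pair); `snv_only` mode restricts to SNV
columns. Neighbor joining is the classical algorithm: minimise
Q(i,j) = (r−2)d(i,j) − R(i) − R(j), Studier–Keppler branch lengths, and the
final three clusters joined at a degree-3 anchor node, giving an unrooted
tree. Ties in Q go to the lexicographically smallest cluster-label pair, so
output is deterministic; negative branch lengths are clamped to zero with
the deficit logged. On additive matrices the output path lengths reproduce
the input to 1e-9, and the implementation is cross-checked against
scikit-bio's independent NJ in the test suite.

Bootstrap resamples alignment columns with replacement per replicate and
scores each internal edge of the base tree by the percentage of replicate
trees containing the same leaf bipartition; supports are stored as integer
internal-node labels. The real-data default is 5000 replicates; tests and
the demo use 20–200 to keep desk-scale runtimes. Rooting places the root at
the midpoint of the edge separating a user-supplied outgroup, which must
form a clade (else an explicit error). Monophyly reports `min_clades`, the
number of maximal query-pure clades — provably the minimum number of clades
whose union is the query on a tree — so 1 ⇔ monophyletic, and a set with
members in both of two sister groups yields 2.

Maximum-likelihood search (e.g. GTR) is intentionally out of scope: the
implemented and tested path is NJ + bootstrap, which suffices for the
plastome-scale divergences the package targets.

## Pipeline

The `run` command executes simulate → structure → phase → variants → tree
from one strictly-validated YAML config (unknown keys rejected; every
stochastic stage requires an explicit seed). Every run writes a manifest
with per-stage wall-clock and SHA-256 checksums of outputs; deterministic
configs reproduce byte-identical checksums. The demo config derives its two
external marker lists from overlapping subsets of the planted SNV positions
— synthetic stand-ins for prior studies' marker lists — so the intersection
stage runs end to end without downloads.

## Problem sizes and numerical choices

Tests and the acceptance script use 4.6–10 kb plastomes (1500–6000 bp LSC,
400–1000 bp IRs), 40–200 reads per simulation, 100-replicate CI
calibrations, 12-leaf populations at ~25 expected substitutions per branch,
and 20–200 bootstrap replicates; these sizes exercise every code path while
keeping the full suite in minutes. Branch-length comparisons use absolute
tolerance 1e-9 (NJ on additive input is exact up to float arithmetic);
distance-matrix symmetry is checked to 1e-12; bootstrap supports are
integer percents.

## Known limitations

- Plastomes lacking IRs, or carrying more than one large repeat family, are
  rejected rather than analysed.
- The mapper is a purpose-built contract for region-level placement of long
  reads on a small circular reference; it is not a general-purpose aligner
  and has no MAPQ model.
- Indel placement in the population simulator is uniform and length-geometric;
  real plastome indels cluster in homopolymers and repeats.
- The non-canonical isoform is modelled as exactly equal length to the
  canonical one; small length differences seen in real assemblies are treated
  as assembly artefacts, not biology.
- `min_clades` is computed on the rooted tree; group naming (e.g. which clade
  is "group I") is left to the user.
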