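"""Quadripartite plastome structure: inverted-repeat detection and partitioning.

A typical plastid genome is a circular molecule laid out as a large single-copy
region (LSC), one inverted-repeat copy (IR1/IRa), a small single-copy region
(SSC), and the second inverted-repeat copy (IR2/IRb, the reverse complement of
IR1).  This module locates the IR pair on a circular sequence, partitions the
genome into the four regions, normalises rotation/orientation for multiple
alignment, and constructs the two structural isoforms that differ by SSC
orientation (the substrate of flip-flop recombination).

Coordinates are 1-based inclusive in all reports; BED output is 0-based
half-open.  Circularity is handled by operating on the doubled sequence and
folding coordinates back; a region whose ``end`` exceeds ``genome_length``
wraps past the origin.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from ._seq import revcomp, rotate
from .errors import ParameterError, StructureError

LABELS = ("LSC", "IR1", "SSC", "IR2")
_SINGLE_COPY = ("LSC", "SSC")
_IR = ("IR1", "IR2")


@dataclass(frozen=True)
class Region:
    """One labelled arc of the circular genome, 1-based inclusive.

    ``end`` may exceed the genome length, in which case the region wraps
    past the origin (e.g. start=9000, end=10500 on a 10 kb genome).
    """

    label: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IRPair:
    """A detected inverted-repeat pair: two equal-length arcs, copy2 = revcomp(copy1)."""

    copy1: tuple[int, int]
    copy2: tuple[int, int]
    length: int
    mismatches: int


@dataclass(frozen=True)
class Partition:
    """LSC / IR1 / SSC / IR2 partition of a circular genome.

    Regions are stored in circular order starting from LSC and tile the
    genome exactly once.
    """

    regions: tuple[Region, ...]
    genome_length: int

    def __post_init__(self):
        labels = [r.label for r in self.regions]
        if sorted(labels) != sorted(LABELS):
            raise StructureError(f"partition must contain exactly {LABELS}, got {labels}")
        if sum(r.length for r in self.regions) != self.genome_length:
            raise StructureError("partition regions do not tile the genome")
        if self.region("IR1").length != self.region("IR2").length:
            raise StructureError("IR copies differ in length")
        if self.region("LSC").length < self.region("SSC").length:
            raise StructureError("LSC must be at least as long as SSC")

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    def extract(self, seq: str, label: str) -> str:
        """Region sequence, following the wrap past the origin if needed."""
        r = self.region(label)
        n = self.genome_length
        if r.end <= n:
            return seq[r.start - 1 : r.end]
        return seq[r.start - 1 :] + seq[: r.end - n]

    @property
    def ir_length(self) -> int:
        return self.region("IR1").length

    def to_bed(self, path, chrom: str = "genome") -> None:
        """Write as BED (0-based half-open); wrapped regions split into two lines."""
        n = self.genome_length
        lines = []
        for r in self.regions:
            if r.end <= n:
                lines.append((r.start - 1, r.end, r.label))
            else:
                lines.append((r.start - 1, n, r.label))
                lines.append((0, r.end - n, r.label))
        with open(path, "w") as fh:
            for s, e, lab in lines:
                fh.write(f"{chrom}\t{s}\t{e}\t{lab}\t0\t+\n")

    @classmethod
    def from_bed(cls, path) -> "Partition":
        rows = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise StructureError(f"{path}:{ln}: expected >=4 BED columns")
            rows.append((int(parts[1]), int(parts[2]), parts[3]))
        by_label: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for s, e, lab in rows:
            by_label[lab].append((s, e))
        n = max(e for _, e, _ in rows)
        regions = []
        for lab, ivs in by_label.items():
            ivs.sort()
            if len(ivs) == 1:
                s, e = ivs[0]
                regions.append(Region(lab, s + 1, e))
            elif len(ivs) == 2 and ivs[0][0] == 0 and ivs[1][1] == n:
                # wrapped region split at the origin
                regions.append(Region(lab, ivs[1][0] + 1, n + ivs[0][1]))
            else:
                raise StructureError(f"cannot reassemble wrapped region {lab} from BED")
        start_of = {r.label: r.start for r in regions}
        lsc_start = start_of["LSC"]
        regions.sort(key=lambda r: (r.start - lsc_start) % n)
        return cls(tuple(regions), n)

    def to_tsv(self, path, chrom: str = "genome") -> None:
        with open(path, "w") as fh:
            fh.write("region\tstart\tend\tlength\tstrand\n")
            for r in self.regions:
                fh.write(f"{r.label}\t{r.start}\t{r.end}\t{r.length}\t{r.strand}\n")


def canonical_layout(lsc_len: int, ir_len: int, ssc_len: int) -> Partition:
    """Partition for a genome laid out LSC, IR1, SSC, IR2 from position 1."""
    n = lsc_len + ssc_len + 2 * ir_len
    a = lsc_len
    b = a + ir_len
    c = b + ssc_len
    return Partition(
        (
            Region("LSC", 1, a),
            Region("IR1", a + 1, b),
            Region("SSC", b + 1, c),
            Region("IR2", c + 1, n),
        ),
        n,
    )


# ---------------------------------------------------------------------------
# inverted repeat detection
# ---------------------------------------------------------------------------

def find_inverted_repeats(
    seq: str,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.01,
    *,
    circular: bool = True,
    k: int = 15,
) -> list[IRPair]:
    """Locate maximal inverted-repeat pairs by seed-and-extend.

    Exact k-mer matches between the sequence and its reverse complement seed
    candidate pairs; seeds sharing an anti-diagonal are merged and greedily
    extended outward while the running mismatch count stays within
    ``floor(max_mismatch_frac * length)``.  Pairs are returned longest first,
    then by copy1 start; coordinates are 1-based inclusive and copy ``end``
    may exceed the genome length for arcs wrapping past the origin.
    """
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        raise ParameterError("empty sequence")
    if min_len < 8:
        raise ParameterError("min_len must be >= 8")
    if not 0.0 <= max_mismatch_frac < 1.0:
        raise ParameterError("max_mismatch_frac must be in [0, 1)")
    k = min(k, min_len)
    S = seq + seq if circular else seq
    m = len(S)
    if n < k:
        return []

    index: dict[str, list[int]] = defaultdict(list)
    for j in range(m - k + 1):
        index[S[j : j + k]].append(j)

    # seeds grouped by anti-diagonal c = i + j + k - 1; positions i and c-i pair up
    diag: dict[int, list[int]] = defaultdict(list)
    for i in range(min(n, m - k + 1)):
        for j in index.get(revcomp(S[i : i + k]), ()):
            if i < j < i + n:
                diag[i + j + k - 1].append(i)

    budget = lambda L: int(max_mismatch_frac * L)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    candidates = {}
    for c, starts in diag.items():
        starts.sort()
        merged: list[list[int]] = []
        for i in starts:
            if merged and i <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], i + k - 1)
            else:
                merged.append([i, i + k - 1])
        for p, q in merged:
            # truncate at the palindrome centre so the two arcs stay disjoint
            q = min(q, (c - 1) // 2)
            if q < p:
                continue
            mism = 0
            while True:
                moved = False
                # left: position p-1 pairs with c-(p-1)
                if p - 1 >= 0 and c - (p - 1) <= m - 1 and q < c - q:
                    add = 0 if comp.get(S[p - 1]) == S[c - p + 1] else 1
                    if mism + add <= budget(q - p + 2):
                        p -= 1
                        mism += add
                        moved = True
                # right: position q+1 pairs with c-(q+1); keep intervals disjoint
                if q + 1 <= m - 1 and c - (q + 1) >= 0 and (q + 1) < c - (q + 1):
                    add = 0 if comp.get(S[q + 1]) == S[c - q - 1] else 1
                    if mism + add <= budget(q - p + 2):
                        q += 1
                        mism += add
                        moved = True
                if not moved:
                    break
            # trim mismatched flanks (greedy extension can leave terminal mismatches)
            while q > p and comp.get(S[p]) != S[c - p]:
                p += 1
                mism -= 1
            while q > p and comp.get(S[q]) != S[c - q]:
                q -= 1
                mism -= 1
            L = q - p + 1
            if L < min_len or mism > budget(L):
                continue
            a = p % n
            b = (c - q) % n
            # the two arcs must be disjoint on the circle
            if (b - a) % n < L or (a - b) % n < L:
                continue
            key = tuple(sorted([(a, L), (b, L)]))
            prev = candidates.get(key)
            if prev is None or mism < prev:
                candidates[key] = mism

    pairs = []
    for ((a, L), (b, _)), mism in candidates.items():
        pairs.append(IRPair((a + 1, a + L), (b + 1, b + L), L, mism))
    pairs.sort(key=lambda pr: (-pr.length, pr.copy1[0]))
    return pairs


def partition_genome(seq: str, pair: IRPair) -> Partition:
    """Partition a circular genome given its IR pair.

    The longer single-copy arc between the IR copies becomes the LSC (ties go
    to the arc starting at the smaller coordinate); regions are returned in
    circular order starting from the LSC, the IR following the LSC being IR1.
    """
    n = len(seq)
    L = pair.length
    sA = pair.copy1[0] - 1
    sB = pair.copy2[0] - 1
    arc1_start = (sA + L) % n
    arc1_len = (sB - arc1_start) % n
    arc2_start = (sB + L) % n
    arc2_len = (sA - arc2_start) % n
    if arc1_len == 0 or arc2_len == 0:
        which = "between copy1 and copy2" if arc1_len == 0 else "between copy2 and copy1"
        raise StructureError(f"IR copies are adjacent: zero-length single-copy arc {which}")
    if arc1_len > arc2_len or (arc1_len == arc2_len and arc1_start <= arc2_start):
        lsc_start, lsc_len = arc1_start, arc1_len
        ir1_start = sB
        ssc_start, ssc_len = arc2_start, arc2_len
        ir2_start = sA
    else:
        lsc_start, lsc_len = arc2_start, arc2_len
        ir1_start = sA
        ssc_start, ssc_len = arc1_start, arc1_len
        ir2_start = sB
    regions = (
        Region("LSC", lsc_start + 1, lsc_start + lsc_len),
        Region("IR1", ir1_start + 1, ir1_start + L),
        Region("SSC", ssc_start + 1, ssc_start + ssc_len),
        Region("IR2", ir2_start + 1, ir2_start + L),
    )
    # shift wrapped starts into [1, n]
    fixed = tuple(
        Region(r.label, (r.start - 1) % n + 1, (r.start - 1) % n + r.length, r.strand)
        for r in regions
    )
    return Partition(fixed, n)


def detect_partition(
    seq: str,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.01,
) -> Partition:
    """Find the IR pair and partition the genome; errors if no (or ambiguous) IRs.

    Genomes lacking a qualifying inverted repeat, or carrying extra large
    repeats unrelated to the top pair, are rejected rather than guessed at.
    """
    pairs = find_inverted_repeats(seq, min_len=min_len, max_mismatch_frac=max_mismatch_frac)
    if not pairs:
        raise StructureError(f"no inverted repeat of length >= {min_len} found")
    top = pairs[0]
    claimed = {top.copy1, top.copy2}
    for other in pairs[1:]:
        if {other.copy1, other.copy2} & claimed:
            continue
        raise StructureError(
            "more than one qualifying repeat pair found; genome is not quadripartite"
        )
    return partition_genome(seq, top)


# ---------------------------------------------------------------------------
# canonical form and isoforms
# ---------------------------------------------------------------------------

def _circular_order(partition: Partition) -> list[Region]:
    n = partition.genome_length
    lsc_start = partition.region("LSC").start
    return sorted(partition.regions, key=lambda r: (r.start - lsc_start) % n)


def _rotated_candidate(seq: str, partition: Partition) -> tuple[str, Partition]:
    """Rotate so LSC starts at position 1 and relabel IRs by circular order."""
    n = len(seq)
    order = _circular_order(partition)
    if [r.label for r in order] not in (
        ["LSC", "IR1", "SSC", "IR2"],
        ["LSC", "IR2", "SSC", "IR1"],
    ):
        raise StructureError("regions do not alternate single-copy and IR")
    lsc = order[0]
    rotated = rotate(seq, (lsc.start - 1) % n)
    lengths = {r.label: r.length for r in order}
    return rotated, canonical_layout(lengths["LSC"], order[1].length, lengths["SSC"])


def _revcomp_partition(partition: Partition, n: int) -> Partition:
    regs = []
    for r in partition.regions:
        s0 = (r.start - 1) % n
        new_s0 = (n - (s0 + r.length) % n) % n
        regs.append(Region(r.label, new_s0 + 1, new_s0 + r.length, r.strand))
    lsc_start = next(r.start for r in regs if r.label == "LSC")
    regs.sort(key=lambda r: (r.start - lsc_start) % n)
    # IR labels are positional: relabel so the IR after the LSC is IR1
    order = [r.label for r in regs]
    if order == ["LSC", "IR2", "SSC", "IR1"]:
        regs = [
            Region({"IR1": "IR2", "IR2": "IR1"}.get(r.label, r.label), r.start, r.end, r.strand)
            for r in regs
        ]
    return Partition(tuple(regs), n)


def canonicalize(seq: str, partition: Partition) -> tuple[str, Partition]:
    """Normalise rotation and orientation for multiple alignment.

    The output starts at LSC position 1 in the order LSC-IR1-SSC-IR2.  Of the
    two global orientations (as given, and reverse-complemented) the
    lexicographically smaller rotated string is chosen, making the result
    invariant under arbitrary rotation and orientation of the input and the
    operation idempotent.
    """
    seq = seq.upper()
    n = len(seq)
    fwd, part_f = _rotated_candidate(seq, partition)
    rev, part_r = _rotated_candidate(revcomp(seq), _revcomp_partition(partition, n))
    return (fwd, part_f) if fwd <= rev else (rev, part_r)


def build_isoform(seq: str, partition: Partition, which: str) -> str:
    """Return the requested structural isoform of a circular genome.

    ``canonical`` is the input itself; ``noncanonical`` has the SSC segment
    replaced by its reverse complement — the product of flip-flop
    recombination between the two IR copies.  Applying ``noncanonical`` twice
    is the identity.
    """
    if which not in ("canonical", "noncanonical"):
        raise ParameterError(f"which must be canonical|noncanonical, got {which!r}")
    n = len(seq)
    if partition.genome_length != n:
        raise StructureError("partition does not match sequence length")
    if which == "canonical":
        return seq
    ssc = partition.region("SSC")
    shift = (ssc.start - 1) % n
    rot = rotate(seq, shift)
    flipped = revcomp(rot[: ssc.length]) + rot[ssc.length :]
    return rotate(flipped, -shift)
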