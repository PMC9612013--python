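"""Phase plastome structural isoforms from long reads.

A long read that fully covers one inverted-repeat copy and anchors into both
flanking single-copy regions pins down the relative orientation of LSC and
SSC, and therefore which of the two co-existing structural conformations it
came from: if the two single-copy anchors align to the canonical reference in
the same orientation the read supports the canonical conformation; opposite
orientations mean the SSC-flipped (non-canonical) conformation.  Reads are
separated into two mutually exclusive conformation sets (never both), the
non-canonical fraction is estimated with a Wilson 95% interval, and departure
from the 1:1 flip-flop equilibrium is tested with an exact two-sided binomial
test.

Mapping uses the package's own contract rather than an external aligner:
exact k-mer seeds chained per (region, strand), alignment identity scored
with edlib, hits gated at identity >= 0.85 with unique best placement on
read-overlap conflicts.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

from ._seq import revcomp
from .errors import FormatError, ParameterError, UndefinedRatioError
from .structure import Partition

_LABEL_ORDER = {"LSC": 0, "IR1": 1, "SSC": 2, "IR2": 3}
_SINGLE_COPY = ("LSC", "SSC")


@dataclass(frozen=True)
class SegmentHit:
    """One local alignment of a read substring to a reference region.

    Read and reference intervals are 1-based inclusive; the reference
    interval is local to the named region.  ``covers_region`` marks hits
    spanning the region end to end.
    """

    label: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    covers_region: bool = False

    @property
    def read_length(self) -> int:
        return self.read_end - self.read_start + 1

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass(frozen=True)
class SpanCall:
    """Conformation call for one read."""

    read_id: str
    call: str  # canonical | noncanonical | unclassified
    spanned_ir: str | None = None
    anchors: tuple[int, int] | None = None
    spanning: bool = False


@dataclass
class PhasingResult:
    """Aggregate phasing outcome over a read set."""

    n_reads: int
    n_spanning: int
    n_canonical: int
    n_noncanonical: int
    n_unclassified_spanning: int
    ratio_noncanonical: float | None
    ci95: tuple[float, float] | None
    p_equal: float | None
    reads_canonical: list[str] = field(default_factory=list)
    reads_noncanonical: list[str] = field(default_factory=list)
    reads_unclassified: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = [
            f"reads\t{self.n_reads}",
            f"spanning\t{self.n_spanning}",
            f"canonical\t{self.n_canonical}",
            f"noncanonical\t{self.n_noncanonical}",
            f"unclassified_spanning\t{self.n_unclassified_spanning}",
        ]
        if self.ratio_noncanonical is not None:
            lines.append(f"ratio_noncanonical\t{self.ratio_noncanonical:.4f}")
            lines.append(f"ci95\t{self.ci95[0]:.4f},{self.ci95[1]:.4f}")
            lines.append(f"p_equal\t{self.p_equal:.4f}")
        return "\n".join(lines) + "\n"


class SegmentMapper:
    """Maps reads against the four regions of a canonicalised reference."""

    def __init__(
        self,
        reference: str,
        partition: Partition,
        k: int = 15,
        min_identity: float = 0.85,
        snap: int = 60,
        max_gap: int = 800,
    ):
        self.partition = partition
        self.k = k
        self.min_identity = min_identity
        self.snap = snap
        self.max_gap = max_gap
        reference = reference.upper()
        self.region_seq = {lab: partition.extract(reference, lab) for lab in _LABEL_ORDER}
        # one combined index: k-mer -> [(label, strand, pos in strand-space)]
        self.index: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
        for lab, seq in self.region_seq.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for p in range(len(s) - k + 1):
                    self.index[s[p : p + k]].append((lab, strand, p))

    def _strand_seq(self, label: str, strand: str) -> str:
        s = self.region_seq[label]
        return s if strand == "+" else revcomp(s)

    def map(self, read: str) -> list[SegmentHit]:
        """All maximal region hits of a read, in read-coordinate order."""
        read = read.upper()
        k = self.k
        if len(read) < k:
            return []
        seeds: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        for r in range(len(read) - k + 1):
            for lab, strand, p in self.index.get(read[r : r + k], ()):
                seeds[(lab, strand)].append((r, p))

        candidates = []
        for (lab, strand), ss in seeds.items():
            ss.sort()
            chains: list[list[int]] = []  # [r1, p1, r2, p2] (seed starts)
            for r, p in ss:
                placed = False
                for ch in chains:
                    dr, dp = r - ch[2], p - ch[3]
                    if 0 <= dr <= self.max_gap and dp > 0 and abs(dr - dp) <= 20 + 0.2 * dr:
                        ch[2], ch[3] = r, p
                        placed = True
                        break
                if not placed:
                    chains.append([r, p, r, p])
            for r1, p1, r2, p2 in chains:
                candidates.append((lab, strand, r1, p1, r2 + k - 1, p2 + k - 1))

        hits = []
        for lab, strand, r1, p1, r2, p2 in candidates:
            L = len(self.region_seq[lab])
            sseq = self._strand_seq(lab, strand)
            # snap chain ends to region boundaries (alignment slop / error gaps)
            if 0 < p1 <= self.snap:
                ext = min(p1, r1)
                r1, p1 = r1 - ext, p1 - ext
            tail = L - 1 - p2
            if 0 < tail <= self.snap:
                ext = min(tail, len(read) - 1 - r2)
                r2, p2 = r2 + ext, p2 + ext
            covers = p1 == 0 and p2 == L - 1
            if covers:
                # exact placement of the full region inside the read
                pad = self.snap + 20
                t1 = max(0, r1 - pad)
                t2 = min(len(read), r2 + 1 + pad)
                res = edlib.align(sseq, read[t1:t2], mode="HW", task="locations")
                if res["editDistance"] < 0:
                    continue
                identity = 1.0 - res["editDistance"] / L
                loc = res["locations"][0]
                r1, r2 = t1 + loc[0], t1 + loc[1]
            else:
                sub_read = read[r1 : r2 + 1]
                sub_ref = sseq[p1 : p2 + 1]
                dist = edlib.align(sub_read, sub_ref, mode="NW", task="distance")["editDistance"]
                identity = 1.0 - dist / max(len(sub_read), len(sub_ref))
            if identity < self.min_identity:
                continue
            if r2 - r1 + 1 < 2 * k and not covers:
                continue  # chance micro-matches carry no placement signal
            if strand == "+":
                q1, q2 = p1, p2
            else:
                q1, q2 = L - 1 - p2, L - 1 - p1
            hits.append(
                SegmentHit(lab, r1 + 1, r2 + 1, q1 + 1, q2 + 1, strand, identity, covers)
            )

        # resolve read-overlap conflicts: most matched bases first (identity x
        # aligned length), then identity, then a fixed label/strand order so
        # IR1(+) wins its exact tie with IR2(-)
        hits.sort(
            key=lambda h: (
                -h.identity * h.read_length,
                -h.identity,
                _LABEL_ORDER[h.label],
                h.strand,
            )
        )
        kept: list[SegmentHit] = []
        for h in hits:
            ok = True
            for g in kept:
                ov = min(h.read_end, g.read_end) - max(h.read_start, g.read_start) + 1
                if ov > min(150, 0.5 * min(h.read_length, g.read_length)):
                    ok = False
                    break
            if ok:
                kept.append(h)
        kept.sort(key=lambda h: h.read_start)
        return kept


def map_read_segments(
    read: str,
    reference: str,
    partition: Partition,
    **mapper_kwargs,
) -> list[SegmentHit]:
    """One-shot convenience wrapper around :class:`SegmentMapper`."""
    return SegmentMapper(reference, partition, **mapper_kwargs).map(read)


def classify_spanning_read(
    hits: list[SegmentHit],
    partition: Partition,
    anchor_min: int = 500,
    read_id: str = "",
) -> SpanCall:
    """Call the conformation of one read from its ordered segment hits.

    A read is spanning iff some IR region is fully covered by one hit with
    single-copy hits on both sides; the call requires both anchors to reach
    ``anchor_min`` bp into their regions.  Reads spanning both IRs yield two
    orientation comparisons which must agree; disagreement (or any other
    irregularity) falls back to ``unclassified``, never an exception.
    """
    calls = []
    spanning = False
    spanned_ir = None
    anchors = None
    for a, b, c in zip(hits, hits[1:], hits[2:]):
        if b.label not in ("IR1", "IR2") or not b.covers_region:
            continue
        if a.label not in _SINGLE_COPY or c.label not in _SINGLE_COPY or a.label == c.label:
            continue
        spanning = True
        spanned_ir = spanned_ir or b.label
        if a.ref_length < anchor_min or c.ref_length < anchor_min:
            continue
        if anchors is None:
            anchors = (a.ref_length, c.ref_length)
        calls.append("canonical" if a.strand == c.strand else "noncanonical")
    if not calls or len(set(calls)) > 1:
        return SpanCall(read_id, "unclassified", spanned_ir, None, spanning)
    return SpanCall(read_id, calls[0], spanned_ir, anchors, True)


def estimate_ratio(n_canonical: int, n_noncanonical: int):
    """Non-canonical read fraction with Wilson 95% CI and exact binomial test.

    ``p_equal`` tests the observed counts against the 1:1 flip-flop
    equilibrium (two-sided exact binomial at p0 = 0.5, summing outcome
    probabilities no larger than the observed outcome's).
    """
    if n_canonical < 0 or n_noncanonical < 0:
        raise ParameterError("counts must be non-negative")
    n = n_canonical + n_noncanonical
    if n == 0:
        raise UndefinedRatioError("no classified spanning reads: ratio undefined")
    ratio = n_noncanonical / n
    lo, hi = proportion_confint(n_noncanonical, n, alpha=0.05, method="wilson")
    p = binomtest(n_noncanonical, n, 0.5, alternative="two-sided").pvalue
    return ratio, (float(lo), float(hi)), float(p)


def _read_fastq(path):
    from Bio import SeqIO

    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            yield rec
    except ValueError as exc:
        raise FormatError(f"unreadable FASTQ {path} at record {i if 'i' in dir() else 0}: {exc}") from exc


def phase_reads(
    reads,
    reference: str,
    partition: Partition,
    anchor_min: int = 500,
    out_dir=None,
    min_identity: float = 0.85,
) -> tuple[PhasingResult, dict[str, SpanCall]]:
    """Classify every read and separate the conformation read sets.

    ``reads`` is a FASTQ path or an iterable of Biopython SeqRecords.  When
    ``out_dir`` is given, three FASTQ files are written (canonical,
    noncanonical, unclassified — the last holds unclassified and non-spanning
    reads so the two conformation sets stay mutually exclusive) plus a
    per-read call TSV and a summary report.
    """
    from Bio import SeqIO

    if isinstance(reads, (str, Path)):
        records = list(_read_fastq(reads))
    else:
        records = list(reads)
    mapper = SegmentMapper(reference, partition, min_identity=min_identity)
    calls: dict[str, SpanCall] = {}
    buckets = {"canonical": [], "noncanonical": [], "unclassified": []}
    for rec in records:
        hits = mapper.map(str(rec.seq))
        call = classify_spanning_read(hits, partition, anchor_min, read_id=rec.id)
        calls[rec.id] = call
        buckets[call.call].append(rec)

    n_can = len(buckets["canonical"])
    n_non = len(buckets["noncanonical"])
    n_unc_span = sum(1 for c in calls.values() if c.spanning and c.call == "unclassified")
    if n_can + n_non:
        ratio, ci, p = estimate_ratio(n_can, n_non)
    else:
        ratio = ci = p = None
    result = PhasingResult(
        n_reads=len(records),
        n_spanning=n_can + n_non + n_unc_span,
        n_canonical=n_can,
        n_noncanonical=n_non,
        n_unclassified_spanning=n_unc_span,
        ratio_noncanonical=ratio,
        ci95=ci,
        p_equal=p,
        reads_canonical=[r.id for r in buckets["canonical"]],
        reads_noncanonical=[r.id for r in buckets["noncanonical"]],
        reads_unclassified=[r.id for r in buckets["unclassified"]],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, recs in buckets.items():
            with open(out / f"{name}.fastq", "w") as fh:
                SeqIO.write(recs, fh, "fastq")
        rows = [
            {
                "read": rid,
                "call": c.call,
                "spanning": c.spanning,
                "spanned_ir": c.spanned_ir or "",
                "anchor_left": c.anchors[0] if c.anchors else "",
                "anchor_right": c.anchors[1] if c.anchors else "",
            }
            for rid, c in calls.items()
        ]
        pd.DataFrame(rows).to_csv(out / "calls.tsv", sep="\t", index=False)
        (out / "phasing_report.txt").write_text(result.report())
    return result, calls


def collapsed_depth_ratio(hit_lists, partition: Partition) -> float:
    """IR depth over single-copy depth on the collapsed (single-IR) representation.

    Both IR copies of the quadripartite genome collapse onto one repeat unit,
    so with the two copies present in the molecule the repeat accumulates
    about twice the read depth of the single-copy regions.
    """
    ir_bases = sc_bases = 0
    for hits in hit_lists:
        for h in hits:
            if h.label in ("IR1", "IR2"):
                ir_bases += h.ref_length
            else:
                sc_bases += h.ref_length
    ir_len = partition.ir_length
    sc_len = partition.region("LSC").length + partition.region("SSC").length
    if sc_bases == 0:
        raise ParameterError("no single-copy coverage")
    return (ir_bases / ir_len) / (sc_bases / sc_len)
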