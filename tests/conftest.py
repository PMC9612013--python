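"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

import plastokit as pk

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_force_inverted_repeats(seq: str, min_len: int, circular: bool = True):
    """O(n^2) exact maximal inverted-repeat pairs, by anti-diagonal scan.

    Independent of the package's seed-and-extend path: walks every
    anti-diagonal of the (doubled) sequence, collects maximal exact match
    runs, truncates at the palindrome centre, folds to circle coordinates
    and deduplicates.  Exact matches only (mismatch budget 0).
    """
    seq = seq.upper()
    n = len(seq)
    S = seq + seq if circular else seq
    m = len(S)
    found = set()
    for c in range(2 * m - 1):
        lo, hi = max(0, c - m + 1), min(m - 1, c)
        run_start = None
        for x in range(lo, hi + 2):
            match = x <= hi and _COMP.get(S[x]) == S[c - x]
            if match and run_start is None:
                run_start = x
            elif not match and run_start is not None:
                a, b = run_start, x - 1
                run_start = None
                q = min(b, (c - 1) // 2)  # keep the two arcs disjoint
                L = q - a + 1
                if q < a or L < min_len:
                    continue
                i1, i2 = a % n, (c - q) % n
                if (i2 - i1) % n < L or (i1 - i2) % n < L:
                    continue
                found.add(tuple(sorted([(i1, L), (i2, L)])))
    return sorted(
        (pk.IRPair((a + 1, a + L), (b + 1, b + L), L, 0) for (a, L), (b, _) in found),
        key=lambda p: (-p.length, p.copy1[0]),
    )


def truth_spanning_reads(truth, partition, genome_length: int, anchor_min: int = 500):
    """Reads whose true placement fully covers an IR copy plus ``anchor_min``
    bp into both flanking single-copy regions (computed from truth records,
    never from the mapper)."""
    spanning = {}
    for _, row in truth.iterrows():
        for lab in ("IR1", "IR2"):
            r = partition.region(lab)
            for off in (0, genome_length):
                s0, e0 = r.start - 1 + off, r.end + off
                if row.start <= s0 - anchor_min and row.start + row.length >= e0 + anchor_min:
                    spanning[row.read] = lab
    return spanning


def scan_columns_oracle(ids, seqs, min_minor_count=1):
    """Per-column scan classifying SNVs and indel events, written plainly."""
    ncol = len(seqs[0])
    snvs = []
    for col in range(ncol):
        column = [s[col] for s in seqs]
        if "-" in column:
            continue
        counts = {}
        for b in column:
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        if len(counts) >= 2 and sum(counts.values()) - max(counts.values()) >= min_minor_count:
            snvs.append(col + 1)
    events = []
    prev = None
    for col in range(ncol):
        column = [s[col] for s in seqs]
        pattern = tuple(b == "-" for b in column)
        if any(pattern) and not all(pattern):
            if pattern == prev:
                events[-1][1] = col + 1
            else:
                events.append([col + 1, col + 1, pattern])
            prev = pattern
        else:
            prev = None
    return snvs, [(s, e) for s, e, _ in events]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SMALL_SPEC = pk.PlastomeSpec(lsc_len=3000, ssc_len=800, ir_len=400, gc_content=0.5, seed=1)


@pytest.fixture(scope="session")
def small_genome():
    seq, partition = pk.simulate_plastome(SMALL_SPEC)
    return seq, partition


@pytest.fixture(scope="session")
def toy_alignment():
    """The 3-sequence, 9-column worked example: one SNV (col 3), one 1-column indel (col 7)."""
    return pk.Alignment(["s1", "s2", "s3"], ["ACGTAC-GT", "ACATAC-GT", "ACGTACCGT"])


@pytest.fixture(scope="session")
def phasing_setup():
    """10 kb plastome with 1 kb IRs, error-free 200-read mixture at 0.5."""
    spec = pk.PlastomeSpec(lsc_len=6000, ssc_len=2000, ir_len=1000, gc_content=0.38, seed=3)
    seq, partition = pk.simulate_plastome(spec)
    iso_b = pk.build_isoform(seq, partition, "noncanonical")
    params = pk.ReadSimParams(
        n_reads=200, length_mean=3500, length_sd=600,
        mismatch_rate=0.0, ins_rate=0.0, del_rate=0.0, mixture_ratio=0.5, seed=4,
    )
    records, truth = pk.simulate_reads(seq, iso_b, params)
    return seq, partition, iso_b, records, truth
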