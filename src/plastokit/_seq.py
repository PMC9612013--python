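"""Low-level DNA string helpers shared across modules."""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(b: str) -> str:
    return b.translate(_COMPLEMENT)


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that 0-based ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def random_dna(rng: np.random.Generator, length: int, gc_content: float) -> str:
    """i.i.d. random DNA with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(bases)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
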