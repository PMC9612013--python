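"""Ground-truthed synthetic plastomes, read sets, and populations.

Everything downstream of this module (structure detection, isoform phasing,
variant extraction, tree building) is exercised on data generated here, with
complete truth tables: per-read origin records, per-site variant records, and
the planted quadripartite partition.  All generators are bit-reproducible
under a fixed seed.

The substitution process is single-site Jukes–Cantor with Poisson event
counts per branch; indels are gap events with geometric lengths.  Read
lengths are log-normal, truncated to [200 bp, genome length]; circularity is
emulated by sampling from the doubled sequence.  FASTQ qualities are a
constant Phred 20 and are not used downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import random_dna, revcomp
from .errors import ParameterError
from .structure import Partition, canonical_layout, find_inverted_repeats, build_isoform
from .variants import Alignment

MIN_READ_LEN = 200
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass(frozen=True)
class PlastomeSpec:
    """Parameters of a synthetic quadripartite plastome.

    Defaults are maize-plastome-like: ~140 kb total, an ~82 kb LSC, and an
    SSC flanked by two ~22.8 kb inverted repeats, at plastid GC content.
    """

    lsc_len: int = 82_000
    ssc_len: int = 12_500
    ir_len: int = 22_750
    gc_content: float = 0.385
    seed: int = 0

    def __post_init__(self):
        if self.lsc_len <= 0 or self.ssc_len <= 0:
            raise ParameterError("region lengths must be positive")
        if self.ir_len < 1:
            raise ParameterError("ir_len must be >= 1")
        if self.lsc_len <= self.ssc_len:
            raise ParameterError("LSC must be longer than SSC")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ParameterError("gc_content must be in [0, 1]")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class ReadSimParams:
    """Long-read simulation parameters (CLR-like error profile by default).

    ``mixture_ratio`` is the probability that a read originates from the
    non-canonical isoform; the default 0.5 emulates the near-1:1 isoform
    equilibrium expected under rapid flip-flop recombination.
    """

    n_reads: int = 200
    length_mean: float = 12_000.0
    length_sd: float = 8_000.0
    mismatch_rate: float = 0.03
    ins_rate: float = 0.06
    del_rate: float = 0.03
    mixture_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ParameterError("n_reads must be non-negative")
        for name in ("mismatch_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.mismatch_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ParameterError("error rates must sum to < 1")
        if not 0.0 <= self.mixture_ratio <= 1.0:
            raise ParameterError("mixture_ratio must be in [0, 1]")
        if self.length_mean <= 0 or self.length_sd < 0:
            raise ParameterError("length_mean must be > 0 and length_sd >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Evolve a population of genomes on a known tree.

    ``tree`` is a rooted newick string (or dendropy Tree) with branch lengths
    in expected substitutions per site; ``indel_rate`` is gap events per site
    per unit branch length, with geometric(``indel_len_geom_p``) lengths.
    """

    tree: object
    subst_rate_scale: float = 1.0
    indel_rate: float = 0.0
    indel_len_geom_p: float = 0.5
    seed: int = 0


@dataclass
class TruthTables:
    """Complete ground truth of one simulation."""

    read_truth: pd.DataFrame | None = None
    variant_truth: pd.DataFrame | None = None
    partition_truth: Partition | None = None


# ---------------------------------------------------------------------------
# genome and isoforms
# ---------------------------------------------------------------------------

def simulate_plastome(spec: PlastomeSpec) -> tuple[str, Partition]:
    """Generate a circular quadripartite genome and its planted partition.

    Layout from position 1 is LSC, IR1, SSC, IR2 with IR2 = revcomp(IR1).
    Single-copy regions are rejection-resampled so they contain no spurious
    inverted repeat of IR length, and the bases flanking the planted repeat
    are constrained so the pair is maximal — the planted partition is then
    the unique answer a correct detector can return.
    """
    rng = np.random.default_rng(spec.seed)
    n_l, n_s, n_i = spec.lsc_len, spec.ssc_len, spec.ir_len
    for _ in range(100):
        lsc = random_dna(rng, n_l, spec.gc_content)
        ssc = random_dna(rng, n_s, spec.gc_content)
        ir1 = random_dna(rng, n_i, spec.gc_content)
        if n_i >= 8:
            spurious = find_inverted_repeats(
                lsc + ssc, min_len=n_i, max_mismatch_frac=0.0, circular=False
            )
            if spurious:
                continue
        seq = list(lsc + ir1 + ssc + revcomp(ir1))
        # keep the planted repeat maximal: outward extension pairs the last
        # LSC base with the first genome base; inward extension pairs the
        # first and last SSC bases
        def _redraw_until(idx: int, forbidden: str):
            while seq[idx] == forbidden:
                seq[idx] = random_dna(rng, 1, spec.gc_content)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        _redraw_until(n_l - 1, comp[seq[0]])
        _redraw_until(n_l + n_i, comp[seq[n_l + n_i + n_s - 1]])
        return "".join(seq), canonical_layout(n_l, n_i, n_s)
    raise ParameterError("could not generate a spurious-repeat-free genome")


def make_isoform(sequence: str, partition: Partition, which: str) -> str:
    """Canonical or SSC-flipped isoform; see :func:`plastokit.structure.build_isoform`."""
    return build_isoform(sequence, partition, which)


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def _apply_errors(frag: str, params: ReadSimParams, rng: np.random.Generator) -> str:
    if params.mismatch_rate == params.ins_rate == params.del_rate == 0.0:
        return frag
    u = rng.random(len(frag))
    v = rng.random(len(frag))
    subs = rng.integers(0, 3, size=len(frag))
    ins_bases = rng.integers(0, 4, size=len(frag))
    out = []
    d, m = params.del_rate, params.mismatch_rate
    for i, b in enumerate(frag):
        x = u[i]
        if x < d:
            pass  # deletion
        elif x < d + m:
            out.append(_OTHER[b][subs[i]])
        else:
            out.append(b)
        if v[i] < params.ins_rate:
            out.append("ACGT"[ins_bases[i]])
    return "".join(out)


def simulate_reads(
    iso_a: str,
    iso_b: str,
    params: ReadSimParams,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw long reads from a two-isoform mixture with per-base errors.

    Each read comes from isoform B with probability ``mixture_ratio``, starts
    at a uniformly random position on the circle, and is reverse-complemented
    with probability 1/2.  Returns Biopython FASTQ records (constant Phred 20)
    and a per-read truth table (read, isoform, start, strand, length).
    """
    if len(iso_a) != len(iso_b):
        raise ParameterError("isoform sequences must have equal length")
    rng = np.random.default_rng(params.seed)
    n = len(iso_a)
    doubled = {"A": iso_a + iso_a, "B": iso_b + iso_b}
    if params.length_sd > 0:
        sigma2 = math.log(1.0 + (params.length_sd / params.length_mean) ** 2)
        mu = math.log(params.length_mean) - sigma2 / 2.0
    records, rows = [], []
    for i in range(params.n_reads):
        iso = "B" if rng.random() < params.mixture_ratio else "A"
        if params.length_sd > 0:
            length = int(round(rng.lognormal(mu, math.sqrt(sigma2))))
        else:
            length = int(round(params.length_mean))
        length = max(MIN_READ_LEN, min(length, n))
        start = int(rng.integers(0, n))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = doubled[iso][start : start + length]
        if strand == "-":
            frag = revcomp(frag)
        read_seq = _apply_errors(frag, params, rng)
        rid = f"read{i:05d}"
        rec = SeqRecord(Seq(read_seq), id=rid, description=f"isoform={iso} start={start} strand={strand}")
        rec.letter_annotations["phred_quality"] = [20] * len(read_seq)
        records.append(rec)
        rows.append((rid, iso, start, strand, length))
    truth = pd.DataFrame(rows, columns=["read", "isoform", "start", "strand", "length"])
    return records, truth


def write_fastq(records: list[SeqRecord], path) -> None:
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# population on a tree
# ---------------------------------------------------------------------------

@dataclass
class PopulationResult:
    """Leaves, true alignment, and planted-variant truth of one simulation."""

    leaves: dict[str, str]
    alignment: Alignment
    column_ancestor_pos: list[int | None]
    variant_truth: pd.DataFrame
    tree: dendropy.Tree


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def simulate_population(ancestor: str, spec: PopulationSpec) -> PopulationResult:
    """Evolve an ancestor sequence down a rooted tree.

    Substitutions are placed by a Poisson process per branch under single-site
    Jukes–Cantor; indels are gap events with geometric lengths.  The returned
    true alignment carries the ancestor coordinate system
    (``column_ancestor_pos``), so planted SNV columns and indel events are
    recoverable exactly.  ``variant_truth`` lists every ancestral site hit by
    a substitution, with the realised allele per leaf and a ``polymorphic``
    flag (>= 2 distinct non-gap leaf alleles).
    """
    ancestor = ancestor.upper()
    if not ancestor:
        raise ParameterError("ancestor sequence is empty")
    tree = _as_tree(spec.tree)
    rng = np.random.default_rng(spec.seed)
    L = len(ancestor)

    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParameterError("leaf labels must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParameterError("negative branch length")

    order: list[int] = list(range(L))  # global column order (keys)
    next_key = L
    sub_sites: set[int] = set()  # ancestral keys hit by a substitution

    root_tokens = [(i, ancestor[i]) for i in range(L)]
    node_tokens: dict[int, list] = {id(tree.seed_node): root_tokens}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        tokens = list(node_tokens[id(node.parent_node)])
        t = node.edge.length or 0.0
        if t > 0 and tokens:
            n_sub = rng.poisson(t * spec.subst_rate_scale * len(tokens))
            for _ in range(n_sub):
                pos = int(rng.integers(0, len(tokens)))
                key, old = tokens[pos]
                new = _OTHER[old][int(rng.integers(0, 3))] if old in _OTHER else old
                tokens[pos] = (key, new)
                if key < L:
                    sub_sites.add(key)
            n_indel = rng.poisson(spec.indel_rate * t * len(tokens)) if spec.indel_rate > 0 else 0
            for _ in range(n_indel):
                g = int(rng.geometric(spec.indel_len_geom_p))
                if rng.random() < 0.5 and tokens:  # deletion
                    pos = int(rng.integers(0, len(tokens)))
                    del tokens[pos : pos + g]
                else:  # insertion
                    pos = int(rng.integers(0, len(tokens) + 1))
                    new_keys = list(range(next_key, next_key + g))
                    next_key += g
                    bases = ["ACGT"[int(b)] for b in rng.integers(0, 4, size=g)]
                    if pos > 0:
                        gidx = order.index(tokens[pos - 1][0]) + 1
                    elif tokens:
                        gidx = order.index(tokens[pos][0])
                    else:
                        gidx = len(order)
                    order[gidx:gidx] = new_keys
                    tokens[pos:pos] = list(zip(new_keys, bases))
        node_tokens[id(node)] = tokens

    col_index = {key: i for i, key in enumerate(order)}
    ncol = len(order)
    aligned = {}
    for leaf in tree.leaf_node_iter():
        row = ["-"] * ncol
        for key, base in node_tokens[id(leaf)]:
            row[col_index[key]] = base
        aligned[leaf.taxon.label] = "".join(row)
    alignment = Alignment(list(aligned.keys()), list(aligned.values()))
    column_ancestor_pos = [key + 1 if key < L else None for key in order]

    rows = []
    for key in sorted(sub_sites):
        col = col_index[key]
        alleles = {lab: aligned[lab][col] for lab in aligned}
        distinct = {a for a in alleles.values() if a not in ("-", "N")}
        rows.append(
            {
                "ancestor_pos": key + 1,
                "aln_col": col + 1,
                "ancestral_allele": ancestor[key],
                "polymorphic": len(distinct) >= 2,
                "has_gap": "-" in alleles.values(),
                **{f"allele_{lab}": a for lab, a in alleles.items()},
            }
        )
    cols = ["ancestor_pos", "aln_col", "ancestral_allele", "polymorphic", "has_gap"]
    variant_truth = pd.DataFrame(rows, columns=cols + [f"allele_{lab}" for lab in aligned]) \
        if rows else pd.DataFrame(columns=cols)
    leaves = {lab: s.replace("-", "") for lab, s in aligned.items()}
    return PopulationResult(leaves, alignment, column_ancestor_pos, variant_truth, tree)


def two_clade_newick(
    n_per_clade: int,
    branch_length: float,
    outgroup: str | None = None,
    outgroup_branch: float | None = None,
    prefixes: tuple[str, str] = ("A", "B"),
) -> str:
    """Balanced two-clade rooted newick, every branch ``branch_length`` long.

    Handy synthetic analogue of a population split into two plastid lineages,
    optionally with a divergent outgroup hung off the root.
    """

    def clade(labels: list[str]) -> str:
        if len(labels) == 1:
            return f"{labels[0]}:{branch_length}"
        mid = len(labels) // 2
        return f"({clade(labels[:mid])},{clade(labels[mid:])}):{branch_length}"

    a = clade([f"{prefixes[0]}{i + 1}" for i in range(n_per_clade)])
    b = clade([f"{prefixes[1]}{i + 1}" for i in range(n_per_clade)])
    if outgroup is None:
        return f"({a},{b});"
    ob = outgroup_branch if outgroup_branch is not None else 4 * branch_length
    return f"(({a},{b}):{branch_length},{outgroup}:{ob});"
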