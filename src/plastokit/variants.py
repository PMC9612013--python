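"""SNV / indel classification of whole-plastome alignments, lift-over, markers.

An alignment column is an SNV iff it contains no gap character and shows at
least two distinct alleles among {A,C,G,T} with the minor-allele count at or
above ``min_minor_count`` (default 1: no low-frequency filtering, so
singleton alleles count).  N is missing data and never creates an SNV.
Gap-containing columns belong to indel events instead: an event is a maximal
run of adjacent columns sharing an identical, non-trivial gap
presence/absence pattern.  The two classes are disjoint by construction.

Because external marker lists are reported in reference coordinates while
SNVs live in alignment columns, a gap-aware coordinate map lifts positions
between the two systems.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

_MISSING = ("-", "N")


@dataclass
class Alignment:
    """A multiple sequence alignment over {A,C,G,T,N,-}.

    Sequences are upper-cased on construction; all rows must share one
    length and ids must be unique.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        self.ids = list(self.ids)
        self.seqs = [s.upper() for s in self.seqs]
        if len(self.ids) != len(self.seqs):
            raise FormatError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids")
        if self.seqs:
            ln = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != ln:
                    raise FormatError(f"aligned sequence {sid!r} has ragged length {len(s)} != {ln}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    def matrix(self) -> np.ndarray:
        """(n_seqs, n_columns) array of single characters."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(self.n_seqs, -1)

    def row(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        return read_alignment(path)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, s in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{s}\n")


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA; errors name the first ragged-length record."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"{path}: no FASTA records")
    return Alignment(ids, seqs)


@dataclass
class VariantTable:
    """Classified SNV columns.

    ``table`` has one row per SNV with 1-based alignment position, per-sequence
    alleles, the allele-count summary, and the minor-allele count; ``ref_pos``
    is filled by lift-over against a chosen reference.
    """

    table: pd.DataFrame

    @property
    def n_snvs(self) -> int:
        return len(self.table)

    def positions(self) -> list[int]:
        return self.table["aln_pos"].tolist()


@dataclass
class IndelEvents:
    """Maximal runs of alignment columns sharing one gap pattern."""

    table: pd.DataFrame

    @property
    def n_events(self) -> int:
        return len(self.table)

    @property
    def n_columns(self) -> int:
        """Total gap-containing columns (the column-count alternative tally)."""
        return int((self.table["end"] - self.table["start"] + 1).sum()) if len(self.table) else 0


def classify_columns(al: Alignment, min_minor_count: int = 1) -> tuple[VariantTable, IndelEvents]:
    """Classify every alignment column as SNV, part of an indel event, or invariant."""
    if al.n_seqs == 0 or al.length == 0:
        raise ParameterError("alignment is empty")
    if min_minor_count < 1:
        raise ParameterError("min_minor_count must be >= 1")
    M = al.matrix()
    gaps = M == b"-"
    has_gap = gaps.any(axis=0)

    counts = np.stack([(M == base).sum(axis=0) for base in (b"A", b"C", b"G", b"T")])
    n_alleles = (counts > 0).sum(axis=0)
    total = counts.sum(axis=0)
    minor = total - counts.max(axis=0)
    snv_mask = (~has_gap) & (n_alleles >= 2) & (minor >= min_minor_count)

    snv_rows = []
    for col in np.flatnonzero(snv_mask):
        alleles = {sid: al.seqs[i][col] for i, sid in enumerate(al.ids)}
        cnt = {b: int(counts["ACGT".index(b), col]) for b in "ACGT" if counts["ACGT".index(b), col]}
        snv_rows.append(
            {
                "aln_pos": int(col) + 1,
                "ref_pos": pd.NA,
                "allele_counts": ";".join(f"{b}={c}" for b, c in sorted(cnt.items())),
                "minor_count": int(minor[col]),
                **{f"allele_{sid}": a for sid, a in alleles.items()},
            }
        )
    snv_cols = ["aln_pos", "ref_pos", "allele_counts", "minor_count"] + [
        f"allele_{sid}" for sid in al.ids
    ]
    vt = VariantTable(pd.DataFrame(snv_rows, columns=snv_cols))

    indel_rows = []
    run_start, run_pattern = None, None
    for col in range(al.length + 1):
        pattern = tuple(gaps[:, col]) if col < al.length and has_gap[col] else None
        if pattern is not None and not all(pattern):
            pass
        elif pattern is not None:
            pattern = None  # all-gap column would be trivial; treat as separator
        if pattern == run_pattern and pattern is not None:
            continue
        if run_pattern is not None:
            indel_rows.append(
                {
                    "start": run_start + 1,
                    "end": col,
                    "length": col - run_start,
                    "pattern": "".join("1" if g else "0" for g in run_pattern),
                }
            )
        run_start, run_pattern = (col, pattern) if pattern is not None else (None, None)
    ie = IndelEvents(pd.DataFrame(indel_rows, columns=["start", "end", "length", "pattern"]))
    return vt, ie


# ---------------------------------------------------------------------------
# coordinate lift-over
# ---------------------------------------------------------------------------

@dataclass
class CoordinateMap:
    """Monotone map between alignment columns and ungapped reference positions."""

    reference_id: str
    _aln_to_ref: np.ndarray  # 0 where the reference is gapped, else 1-based ref pos
    _ref_to_aln: np.ndarray  # 1-based alignment column per reference position

    @classmethod
    def build(cls, al: Alignment, reference_id: str) -> "CoordinateMap":
        if reference_id not in al.ids:
            raise ParameterError(f"unknown reference id {reference_id!r}")
        row = np.frombuffer(al.row(reference_id).encode(), dtype="S1")
        nongap = row != b"-"
        aln_to_ref = np.where(nongap, np.cumsum(nongap), 0)
        ref_to_aln = np.flatnonzero(nongap) + 1
        return cls(reference_id, aln_to_ref, ref_to_aln)

    @property
    def reference_length(self) -> int:
        return len(self._ref_to_aln)

    @property
    def alignment_length(self) -> int:
        return len(self._aln_to_ref)

    def to_ref(self, aln_pos: int) -> int | None:
        if not 1 <= aln_pos <= self.alignment_length:
            raise ParameterError(f"alignment position {aln_pos} out of range")
        v = int(self._aln_to_ref[aln_pos - 1])
        return v or None

    def to_alignment(self, ref_pos: int) -> int:
        if not 1 <= ref_pos <= self.reference_length:
            raise ParameterError(f"reference position {ref_pos} out of range")
        return int(self._ref_to_aln[ref_pos - 1])


def build_coordinate_map(al: Alignment, reference_id: str) -> CoordinateMap:
    return CoordinateMap.build(al, reference_id)


def liftover(cmap: CoordinateMap, position: int, direction: str) -> int | None:
    """Map a position between coordinate systems.

    ``direction`` is ``"to_ref"`` (alignment column -> reference position,
    None on a reference-gap column) or ``"to_alignment"``.
    """
    if direction == "to_ref":
        return cmap.to_ref(position)
    if direction == "to_alignment":
        return cmap.to_alignment(position)
    raise ParameterError(f"direction must be to_ref|to_alignment, got {direction!r}")


# ---------------------------------------------------------------------------
# marker intersection
# ---------------------------------------------------------------------------

@dataclass
class MarkerIntersection:
    """Overlap of SNV reference positions with two external marker lists.

    ``high_confidence`` is the three-way intersection — positions seen in this
    alignment and in both prior studies.
    """

    snv_ref_positions: set[int]
    shared_with_a: set[int]
    shared_with_b: set[int]
    high_confidence: set[int]
    n_unmapped_snvs: int

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "n_snvs_mapped": len(self.snv_ref_positions),
            "n_shared_with_a": len(self.shared_with_a),
            "n_shared_with_b": len(self.shared_with_b),
            "n_high_confidence": len(self.high_confidence),
            "n_unmapped_snvs": self.n_unmapped_snvs,
        }


def read_position_list(path) -> set[int]:
    """Single-column TSV of 1-based reference positions (``#`` comments allowed)."""
    positions = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        field = s.split("\t")[0]
        try:
            positions.add(int(field))
        except ValueError:
            raise FormatError(f"{path}:{ln}: not an integer position: {field!r}") from None
    return positions


def intersect_markers(
    snvs: VariantTable,
    cmap: CoordinateMap,
    list_a,
    list_b,
) -> MarkerIntersection:
    """Lift SNVs to reference coordinates and intersect with two marker lists.

    ``list_a`` / ``list_b`` may be file paths or iterables of positions.  SNVs
    falling on reference-gap columns cannot be compared and are only counted.
    """
    set_a = read_position_list(list_a) if isinstance(list_a, (str, Path)) else set(map(int, list_a))
    set_b = read_position_list(list_b) if isinstance(list_b, (str, Path)) else set(map(int, list_b))
    mapped, unmapped = set(), 0
    for pos in snvs.positions():
        ref = cmap.to_ref(pos)
        if ref is None:
            unmapped += 1
        else:
            mapped.add(ref)
    shared_a = mapped & set_a
    shared_b = mapped & set_b
    return MarkerIntersection(mapped, shared_a, shared_b, shared_a & shared_b, unmapped)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_variants(
    vt: VariantTable,
    cmap: CoordinateMap,
    reference_seq: str,
    tsv_path,
    vcf_path,
    chrom: str | None = None,
) -> None:
    """Write the SNV table as TSV and minimal VCFv4.2 in reference coordinates.

    The VCF REF allele is checked against the reference sequence; a mismatch
    indicates an internal inconsistency and raises.  SNVs on reference-gap
    columns appear in the TSV with an empty ref_pos but are omitted from the
    VCF (they have no reference coordinate).
    """
    chrom = chrom or cmap.reference_id
    reference_seq = reference_seq.upper()
    table = vt.table.copy()
    ref_positions = [cmap.to_ref(p) for p in table["aln_pos"]] if len(table) else []
    if len(table):
        table["ref_pos"] = [p if p is not None else pd.NA for p in ref_positions]
    table.to_csv(tsv_path, sep="\t", index=False)

    allele_cols = [c for c in table.columns if c.startswith("allele_") and c != "allele_counts"]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(reference_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in table.iterrows():
            if pd.isna(row["ref_pos"]):
                continue
            pos = int(row["ref_pos"])
            ref_base = reference_seq[pos - 1]
            observed = {row[c] for c in allele_cols} - {"N", "-"}
            if ref_base not in observed:
                raise FormatError(
                    f"REF mismatch at {chrom}:{pos}: reference has {ref_base}, "
                    f"alignment column shows {sorted(observed)}"
                )
            alts = sorted(observed - {ref_base})
            fh.write(f"{chrom}\t{pos}\t.\t{ref_base}\t{','.join(alts)}\t.\tPASS\t.\n")
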