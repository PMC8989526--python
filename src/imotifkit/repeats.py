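"""Scanning for d(TCCC)n / d(GGGA)n tandem repeats and oligo-dC runs.

The C-rich strand of these repeats can fold into an i-motif (stabilised by
hemiprotonated C:C+ pairs), while the complementary G-rich strand can fold
into a G-quadruplex.  Folding competence is length dependent: G-quadruplexes
form at physiological pH once the repeat carries more than three GGGA copies,
whereas i-motifs need at least seven TCCC copies to form detectably at
neutral pH and nine or more copies before the transitional pH rises above 7.
Elements are always reported in the frame of the C-rich strand, which is the
strand on which 5'-oriented deletions are observed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "G4_COMPETENT",
    "IMOTIF_NEUTRAL_PH",
    "IMOTIF_PHT_ABOVE_7",
    "RepeatElement",
    "CRunAnnotation",
    "find_elements",
    "annotate_c_runs",
    "scan_fasta",
    "write_bed",
    "reverse_complement",
]

# Folding-competence flags (thresholds on the whole-unit copy number n)
G4_COMPETENT = "G4_COMPETENT"            # n > 3
IMOTIF_NEUTRAL_PH = "IMOTIF_NEUTRAL_PH"  # n >= 7
IMOTIF_PHT_ABOVE_7 = "IMOTIF_PHT_ABOVE_7"  # n >= 9

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _flags_for(n: int) -> frozenset[str]:
    flags = set()
    if n > 3:
        flags.add(G4_COMPETENT)
    if n >= 7:
        flags.add(IMOTIF_NEUTRAL_PH)
    if n >= 9:
        flags.add(IMOTIF_PHT_ABOVE_7)
    return frozenset(flags)


@dataclass(frozen=True)
class RepeatElement:
    """A maximal whole-unit tandem repeat, reported on the C-rich strand.

    Coordinates are 0-based half-open on the forward strand of the scanned
    sequence; ``c_rich_strand`` records which strand carries the TCCC copies.
    """

    seq_id: str
    start: int
    end: int
    c_rich_strand: str  # "+" or "-"
    n: int
    unit: str = "TCCC"
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.end - self.start != len(self.unit) * self.n:
            raise ValueError("end - start must equal unit length * n")
        if self.c_rich_strand not in ("+", "-"):
            raise ValueError("c_rich_strand must be '+' or '-'")

    @property
    def element_id(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}({self.c_rich_strand}){self.unit}x{self.n}"


@dataclass(frozen=True)
class CRunAnnotation:
    """A maximal run of m cytosines, with the empirical (4n-1) length rule.

    Oligo-dC tracts fold into i-motifs optimally near neutral pH when the
    run length is 11, 15, 19 or 23, i.e. m >= 11 and m = 3 (mod 4).
    """

    start: int
    end: int
    m: int
    conforms_4n_minus_1: bool


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def find_elements(sequence: str, unit: str = "TCCC", min_n: int = 5,
                  seq_id: str = "seq") -> list[RepeatElement]:
    """Find all maximal whole-unit tandem runs of ``unit`` on either strand.

    Runs of ``unit`` itself are reported with the C-rich strand "+"; runs of
    its reverse complement (e.g. GGGA for a TCCC unit) are the same repeat on
    the opposite strand and are reported with the C-rich strand "-".  Only
    whole unit copies are counted; an N breaks a run.  Elements are sorted by
    start coordinate.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    unit = unit.upper()
    if len(unit) != 4 or set(unit) - set("ACGT"):
        raise ValueError("unit must be a 4-mer over ACGT")
    seq = _validate_sequence(sequence)

    elements: list[RepeatElement] = []
    rc_unit = reverse_complement(unit)
    strands = [(unit, "+")] if rc_unit == unit else [(unit, "+"), (rc_unit, "-")]
    for motif, strand in strands:
        for m in re.finditer(f"(?:{motif})+", seq):
            n = (m.end() - m.start()) // 4
            if n >= min_n:
                elements.append(RepeatElement(
                    seq_id=seq_id, start=m.start(), end=m.end(),
                    c_rich_strand=strand, n=n, unit=unit, flags=_flags_for(n)))
    elements.sort(key=lambda e: (e.start, e.c_rich_strand))
    return elements


def annotate_c_runs(sequence: str) -> list[CRunAnnotation]:
    """Annotate every maximal cytosine run with the (4n-1) rule flag."""
    seq = _validate_sequence(sequence)
    runs = []
    for m in re.finditer("C+", seq):
        length = m.end() - m.start()
        runs.append(CRunAnnotation(
            start=m.start(), end=m.end(), m=length,
            conforms_4n_minus_1=(length >= 11 and length % 4 == 3)))
    return runs


def scan_fasta(path, unit: str = "TCCC", min_n: int = 5) -> pd.DataFrame:
    """Scan a (multi-)FASTA file and return a BED6 table of elements.

    Columns: chrom, start, end, name (unit:n), score (copy number), strand
    (C-rich strand).  Rows are ordered by (chrom, start).
    """
    rows = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        for el in find_elements(str(rec.seq), unit=unit, min_n=min_n,
                                seq_id=rec.id):
            rows.append((el.seq_id, el.start, el.end, f"{el.unit}:{el.n}",
                         el.n, el.c_rich_strand))
    if n_records == 0:
        raise ValueError(f"no FASTA records in {path}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "score", "strand"])
    return df.sort_values(["chrom", "start"], kind="mergesort",
                          ignore_index=True)


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
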