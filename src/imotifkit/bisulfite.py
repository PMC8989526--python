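"""Bisulfite clone alignment, C->T conversion calling and deletion calling.

Bisulfite attacks cytosines that are not Watson-Crick paired — unpaired
loops, protonated single strands, and (more slowly) the hemiprotonated C:C+
pairs of an i-motif — deaminating them to uracil, read as T after PCR and
cloning.  Each cloned isolate is globally aligned to the reference region on
the C-rich strand; in bisulfite mode a (ref C, read T) column scores as a
match so conversions are never forced into gaps.  Conversion frequency is
the fraction of scorable reference-C columns read as T.  Gap runs in the
read become deletion events, classified by their position relative to a
repeat element's 5' and 3' boundaries; the deletion frequency counts clones
carrying an event at or upstream of the element (the orientation observed
for i-motif-linked deletions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .repeats import RepeatElement, reverse_complement

__all__ = [
    "SIDE_CLASSES",
    "FIVE_PRIME_CLASSES",
    "ReferenceRegion",
    "AlignedClone",
    "DeletionEvent",
    "ConversionStats",
    "ElementReport",
    "RegionReport",
    "align_clone",
    "call_conversions",
    "call_deletions",
    "classify_deletion",
    "region_report",
    "render_alignment",
]

SIDE_CLASSES = ("UPSTREAM_5P", "OVERLAP_5P", "INTERNAL", "OVERLAP_3P",
                "DOWNSTREAM_3P", "OUTSIDE")
# classes counted as "5'-associated" in the deletion frequency
FIVE_PRIME_CLASSES = frozenset({"UPSTREAM_5P", "OVERLAP_5P", "INTERNAL"})

MATCH = 1.0
MISMATCH = -2.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0

_ALPHABET = "ACGTN"


@dataclass
class ReferenceRegion:
    """A reference region on the C-rich strand with its repeat elements."""

    id: str
    sequence: str
    elements: list[RepeatElement] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        for el in self.elements:
            if el.start < 0 or el.end > len(self.sequence):
                raise ValueError(f"element {el.element_id} outside reference")
            if el.c_rich_strand != "+":
                raise ValueError("elements must be on the + strand in the "
                                 "local C-rich frame")


@dataclass
class AlignedClone:
    """A clone aligned to its reference as (ref, read) columns ('-' = gap)."""

    clone_id: str
    columns: list[tuple[str, str]]
    score: float

    @property
    def reference_text(self) -> str:
        return "".join(r for r, _ in self.columns if r != "-")

    @property
    def read_text(self) -> str:
        return "".join(q for _, q in self.columns if q != "-")


@dataclass(frozen=True)
class DeletionEvent:
    """A maximal gap-in-read run, in 0-based half-open reference coordinates."""

    clone_id: str
    ref_start: int
    ref_end: int
    side_class: str
    element_id: str
    overlap_length: int  # bp of the event inside the element

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class ConversionStats:
    converted: int        # (C, T) columns
    unconverted: int      # (C, C) columns
    excluded_gap: int     # reference C under a read gap
    excluded_other: int   # reference C read as A or G
    frequency: float
    conversions_per_clone_mean: float
    n_clones: int


@dataclass(frozen=True)
class ElementReport:
    element_id: str
    n: int
    conversion: ConversionStats
    deletion_frequency: float
    n_deletion_events: int


@dataclass(frozen=True)
class RegionReport:
    region_id: str
    n_clones: int
    elements: list[ElementReport]
    region_conversion: ConversionStats

    def to_dict(self) -> dict:
        def conv(c: ConversionStats) -> dict:
            return {"converted": c.converted, "unconverted": c.unconverted,
                    "excluded_gap": c.excluded_gap,
                    "excluded_other": c.excluded_other,
                    "frequency": c.frequency,
                    "conversions_per_clone_mean": c.conversions_per_clone_mean}
        return {
            "region_id": self.region_id,
            "n_clones": self.n_clones,
            "region_conversion": conv(self.region_conversion),
            "elements": [
                {"element_id": e.element_id, "n": e.n,
                 "conversion": conv(e.conversion),
                 "deletion_frequency": e.deletion_frequency,
                 "n_deletion_events": e.n_deletion_events}
                for e in self.elements],
        }


@lru_cache(maxsize=4)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if "N" in (a, b):
                m[a, b] = 0.0
            else:
                m[a, b] = MATCH if a == b else MISMATCH
    if mode == "bisulfite":
        m["C", "T"] = MATCH  # deaminated C reads as T: not a mismatch
    elif mode != "standard":
        raise ValueError("mode must be 'bisulfite' or 'standard'")
    aligner.substitution_matrix = m
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_clone(reference: ReferenceRegion, clone: str,
                mode: str = "bisulfite", clone_id: str = "clone") -> AlignedClone:
    """Globally align a clone to the reference with affine gap penalties.

    End gaps are penalised (clones are full-length PCR products).  The clone
    and its reverse complement are both tried and the higher-scoring
    orientation kept (ties keep the forward orientation), so reads need not
    be pre-oriented to the C-rich strand.
    """
    clone = clone.upper()
    if not clone:
        raise ValueError("empty clone sequence")
    if set(clone) - set(_ALPHABET):
        raise ValueError("clone contains characters outside ACGTN")
    ratio = len(clone) / len(reference.sequence)
    if not 0.3 <= ratio <= 1.2:
        raise ValueError(f"clone/reference length ratio {ratio:.2f} outside "
                         "[0.3, 1.2]")
    aligner = _aligner(mode)
    best = None
    for seq in (clone, reverse_complement(clone)):
        aln = aligner.align(reference.sequence, seq)[0]
        if best is None or aln.score > best.score:
            best = aln
    ref_row, read_row = str(best[0]), str(best[1])
    columns = list(zip(ref_row, read_row))
    return AlignedClone(clone_id=clone_id, columns=columns,
                        score=float(best.score))


def _scope_interval(reference_len: int, element: RepeatElement | None,
                    scope: str) -> tuple[int, int]:
    if scope == "region" or element is None:
        return 0, reference_len
    if scope == "element":
        return element.start, element.end
    raise ValueError("scope must be 'element' or 'region'")


def call_conversions(alignments: list[AlignedClone],
                     element: RepeatElement | None = None,
                     scope: str = "element") -> ConversionStats:
    """Tally C->T conversions over all reference-C columns in scope.

    The frequency denominator counts only scorable columns — (C,T)
    converted plus (C,C) unconverted; reference Cs under read gaps or read
    as A/G are tallied separately and excluded.
    """
    if not alignments:
        raise ValueError("no alignments")
    ref_len = len(alignments[0].reference_text)
    lo, hi = _scope_interval(ref_len, element, scope)
    converted = unconverted = exc_gap = exc_other = 0
    per_clone = []
    for aln in alignments:
        if len(aln.reference_text) != ref_len:
            raise ValueError("alignments do not share a reference")
        clone_conv = 0
        pos = 0
        for ref_base, read_base in aln.columns:
            if ref_base == "-":
                continue
            if lo <= pos < hi and ref_base == "C":
                if read_base == "T":
                    converted += 1
                    clone_conv += 1
                elif read_base == "C":
                    unconverted += 1
                elif read_base == "-":
                    exc_gap += 1
                else:
                    exc_other += 1
            pos += 1
        per_clone.append(clone_conv)
    denom = converted + unconverted
    if denom == 0:
        raise ValueError("no scorable cytosine columns in scope")
    return ConversionStats(
        converted=converted, unconverted=unconverted,
        excluded_gap=exc_gap, excluded_other=exc_other,
        frequency=converted / denom,
        conversions_per_clone_mean=sum(per_clone) / len(per_clone),
        n_clones=len(alignments))


def classify_deletion(ref_start: int, ref_end: int, element: RepeatElement,
                      window: int = 50) -> str:
    """Place a deletion event relative to an element's 5'/3' boundaries.

    With element [s, e): UPSTREAM_5P lies wholly in [s-window, s);
    OVERLAP_5P straddles the 5' boundary; INTERNAL lies within the element;
    OVERLAP_3P straddles only the 3' boundary; DOWNSTREAM_3P lies wholly in
    [e, e+window]; anything further away is OUTSIDE.
    """
    s, e = element.start, element.end
    if ref_end <= s:
        return "UPSTREAM_5P" if ref_start >= s - window else "OUTSIDE"
    if ref_start < s:
        return "OVERLAP_5P"
    if ref_end <= e:
        return "INTERNAL"
    if ref_start < e:
        return "OVERLAP_3P"
    return "DOWNSTREAM_3P" if ref_end <= e + window else "OUTSIDE"


def _gap_runs(aln: AlignedClone) -> list[tuple[int, int]]:
    """Maximal runs of read gaps, as half-open reference intervals."""
    runs = []
    pos = 0
    run_start = None
    for ref_base, read_base in aln.columns:
        if ref_base == "-":
            continue  # insertion in read: does not advance a deletion run
        if read_base == "-":
            if run_start is None:
                run_start = pos
        elif run_start is not None:
            runs.append((run_start, pos))
            run_start = None
        pos += 1
    if run_start is not None:
        runs.append((run_start, pos))
    return runs


def call_deletions(alignments: list[AlignedClone], element: RepeatElement,
                   window: int = 50, min_del_len: int = 2,
                   ) -> tuple[list[DeletionEvent], float]:
    """Call deletion events and the 5'-associated deletion frequency.

    Every maximal gap-in-read run of at least ``min_del_len`` bp becomes an
    event.  The deletion frequency is the fraction of clones with at least
    one event classified UPSTREAM_5P, OVERLAP_5P or INTERNAL for the given
    element.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not alignments:
        raise ValueError("no alignments")
    ref_len = len(alignments[0].reference_text)
    if element.start < 0 or element.end > ref_len:
        raise ValueError("element outside reference")
    events = []
    clones_hit = 0
    for aln in alignments:
        hit = False
        for start, end in _gap_runs(aln):
            if end - start < min_del_len:
                continue
            side = classify_deletion(start, end, element, window=window)
            overlap = max(0, min(end, element.end) - max(start, element.start))
            events.append(DeletionEvent(
                clone_id=aln.clone_id, ref_start=start, ref_end=end,
                side_class=side, element_id=element.element_id,
                overlap_length=overlap))
            if side in FIVE_PRIME_CLASSES:
                hit = True
        clones_hit += hit
    return events, clones_hit / len(alignments)


def region_report(reference: ReferenceRegion,
                  clones: list[tuple[str, str]] | list[AlignedClone],
                  mode: str = "bisulfite", window: int = 50,
                  min_del_len: int = 2) -> RegionReport:
    """Align clones (if raw) and aggregate per-element statistics.

    ``clones`` is either a list of (clone_id, sequence) pairs or
    pre-aligned AlignedClone objects sharing this reference.
    """
    if not clones:
        raise ValueError("need at least one clone")
    if isinstance(clones[0], AlignedClone):
        alns = list(clones)
    else:
        alns = [align_clone(reference, seq, mode=mode, clone_id=cid)
                for cid, seq in clones]
    element_reports = []
    for el in reference.elements:
        conv = call_conversions(alns, element=el, scope="element")
        events, freq = call_deletions(alns, el, window=window,
                                      min_del_len=min_del_len)
        element_reports.append(ElementReport(
            element_id=el.element_id, n=el.n, conversion=conv,
            deletion_frequency=freq, n_deletion_events=len(events)))
    region_conv = call_conversions(alns, scope="region")
    return RegionReport(region_id=reference.id, n_clones=len(alns),
                        elements=element_reports,
                        region_conversion=region_conv)


def render_alignment(reference: ReferenceRegion,
                     alignments: list[AlignedClone], width: int = 80) -> str:
    """Plain-text alignment rendering: '.' match, 'T' conversion, '-' deletion.

    Reads are projected onto reference coordinates (read insertions are
    dropped); matching bases print as dots so conversions and deletions
    stand out, the style of published bisulfite clone figures.
    """
    lines = [f"Ref. {reference.sequence}"]
    for aln in alignments:
        row = []
        for ref_base, read_base in aln.columns:
            if ref_base == "-":
                continue
            if read_base == "-":
                row.append("-")
            elif read_base == ref_base:
                row.append(".")
            else:
                row.append(read_base)
        lines.append(f"{aln.clone_id:<4} {''.join(row)}")
    if width and len(reference.sequence) > width:
        blocks = []
        for off in range(0, len(reference.sequence), width):
            for line in lines:
                tag, body = line[:5], line[5:]
                blocks.append(tag + body[off:off + width])
            blocks.append("")
        return "\n".join(blocks)
    return "\n".join(lines)
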