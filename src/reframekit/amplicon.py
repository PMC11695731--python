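"""Amplicon deep-sequencing editing-outcome quantification.

Reads are kept when their mean phred quality exceeds a threshold (default
>30, strict), globally aligned to the amplicon reference with free end
gaps under an affine scheme (match +2, mismatch -4, gap open -10, extend
-1; both orientations tried, better identity kept), and discarded when
identity over the aligned columns falls below the homology floor (default
60%).  Editing calls use a quantification window centered on the blunt-cut
gap index (the sgRNA 3' end offset by -3), default 30 bp wide, with 15 bp
excluded from each amplicon edge.  A read is *modified* iff at least one
indel overlaps the window; substitutions are recorded but never set the
modified status.  A 1-bp insertion of the expected duplicated base within
the homopolymer run abutting the cut is labelled as the templated +1
event.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .coding import revcomp


@dataclass
class AmpliconReference:
    """Amplicon sequence plus quantification-window geometry.

    The spacer may be given in either orientation; its occurrence in the
    amplicon fixes the strand, the cut gap index, and the expected
    templated +1 base.
    """

    sequence: str
    spacer: str
    window_center_offset: int = -3  # relative to the spacer 3' end
    window_size: int = 30
    edge_exclusion_left: int = 15
    edge_exclusion_right: int = 15

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.spacer = self.spacer.upper()
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        fwd = self.sequence.find(self.spacer)
        rev = self.sequence.find(revcomp(self.spacer))
        if fwd >= 0:
            self.spacer_strand = "+"
            self.spacer_start = fwd
            self.cut_index = fwd + 17
        elif rev >= 0:
            self.spacer_strand = "-"
            self.spacer_start = rev
            self.cut_index = rev + 3
        else:
            raise ValueError("spacer not found in amplicon (either strand)")
        # center offset is defined relative to the guide 3' end; the default
        # -3 lands exactly on the blunt-cut gap index on either strand
        delta = self.window_center_offset + 3
        center = self.cut_index + (delta if self.spacer_strand == "+" else -delta)
        half = self.window_size // 2
        self.window = (center - half, center + (self.window_size - half))
        if not (
            self.edge_exclusion_left <= self.window[0]
            and self.window[1] <= len(self.sequence) - self.edge_exclusion_right
        ):
            raise ValueError("quantification window overlaps excluded edges")

    @property
    def expected_plus1_base(self) -> str:
        base_idx = self.cut_index - 1 if self.spacer_strand == "+" else self.cut_index
        return self.sequence[base_idx]


@dataclass(frozen=True)
class SequencedRead:
    read_id: str
    bases: str
    quals: str

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and qualities differ in length")
        if any(not (33 <= ord(c) <= 126) for c in self.quals):
            raise ValueError("qualities must be printable phred33")

    @property
    def mean_quality(self) -> float:
        return sum(ord(c) - 33 for c in self.quals) / len(self.quals)


@dataclass
class AlleleCall:
    read_id: str
    status: str  # unmodified | modified | discarded-quality | discarded-homology
    signature: str | None = None  # canonical edit string or "WT"
    in_window_indels: list[tuple[str, int, int]] = field(default_factory=list)
    n_substitutions: int = 0
    templated_plus1: bool = False


@dataclass
class AlleleFrequencyTable:
    rows: pd.DataFrame  # columns: signature, read_count, frequency
    retained: int
    discarded: int
    percent_modified: float
    percent_templated_plus1: float
    percent_undefined: bool = False

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "retained": self.retained,
            "discarded": self.discarded,
            "percent_modified": self.percent_modified,
            "percent_templated_plus1": self.percent_templated_plus1,
            "percent_undefined": self.percent_undefined,
        }


# ---------------------------------------------------------------------------
# filtering and alignment

def quality_filter(read: SequencedRead, min_mean_q: float = 30.0) -> bool:
    """Keep iff mean phred quality is strictly greater than the threshold."""
    return read.mean_quality > min_mean_q


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    # reads may cover only part of the amplicon: gaps at the reference ends
    # (read starts late / ends early) are free, but the read itself must be
    # consumed end-to-end so junk reads cannot hide behind end gaps
    try:
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute name
        aligner.query_end_gap_score = 0.0
    return aligner

_ALIGNER = _make_aligner()


@dataclass
class AmpliconAlignment:
    """One read aligned to the amplicon, with parsed edits.

    Insertions are (ref gap index, inserted bases); deletions are
    (ref start, ref end) half-open; substitutions are (ref index, read
    base).  Indels are left-normalized against the reference.
    """

    identity: float
    orientation: str  # '+' if the read matched as given
    insertions: list[tuple[int, str]]
    deletions: list[tuple[int, int]]
    substitutions: list[tuple[int, str]]


def _parse_alignment(aln, ref: str) -> AmpliconAlignment:
    a_ref, a_read = str(aln[0]), str(aln[1])
    # trim end-gap columns (leading/trailing gaps in either row)
    start = 0
    while a_ref[start] == "-" or a_read[start] == "-":
        start += 1
    end = len(a_ref)
    while a_ref[end - 1] == "-" or a_read[end - 1] == "-":
        end -= 1
    matches = 0
    columns = end - start
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    substitutions: list[tuple[int, str]] = []
    # reference coordinate at column `start`
    ref_pos = sum(1 for ch in a_ref[:start] if ch != "-")
    i = start
    while i < end:
        if a_ref[i] == "-":
            j = i
            while j < end and a_ref[j] == "-":
                j += 1
            insertions.append((ref_pos, a_read[i:j]))
            i = j
        elif a_read[i] == "-":
            j = i
            while j < end and a_read[j] == "-":
                j += 1
            length = j - i
            deletions.append((ref_pos, ref_pos + length))
            ref_pos += length
            i = j
        else:
            if a_ref[i] == a_read[i]:
                matches += 1
            else:
                substitutions.append((ref_pos, a_read[i]))
            ref_pos += 1
            i += 1
    # left-normalize indels against the reference
    insertions = [_normalize_insertion(ref, g, s) for g, s in insertions]
    deletions = [_normalize_deletion(ref, s, e) for s, e in deletions]
    return AmpliconAlignment(
        identity=matches / columns if columns else 0.0,
        orientation="+",
        insertions=insertions,
        deletions=deletions,
        substitutions=substitutions,
    )


def _normalize_insertion(ref: str, gap: int, bases: str) -> tuple[int, str]:
    while gap > 0 and ref[gap - 1] == bases[-1]:
        bases = ref[gap - 1] + bases[:-1]
        gap -= 1
    return gap, bases


def _normalize_deletion(ref: str, start: int, end: int) -> tuple[int, int]:
    while start > 0 and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def align_to_amplicon(
    read: SequencedRead, ref: AmpliconReference, min_homology: float = 0.60
) -> AmpliconAlignment | None:
    """Align a retained read to the amplicon; None when identity < floor.

    Both the read and its reverse complement are aligned; the orientation
    with the higher identity is kept.
    """
    best: AmpliconAlignment | None = None
    best_score = None
    for orient, seq in (("+", read.bases), ("-", revcomp(read.bases))):
        seq = seq.replace("N", "A")  # N never matches anyway under phred33 sims
        aln = _ALIGNER.align(ref.sequence, seq)[0]
        if best_score is not None and aln.score <= best_score:
            continue
        parsed = _parse_alignment(aln, ref.sequence)
        parsed.orientation = orient
        best, best_score = parsed, aln.score
    if best is None or best.identity < min_homology:
        return None
    return best


# ---------------------------------------------------------------------------
# edit calling

def _fmt_offset(delta: int) -> str:
    return "cut" if delta == 0 else f"cut{delta:+d}"


def call_edits(
    read_id: str, alignment: AmpliconAlignment, ref: AmpliconReference
) -> AlleleCall:
    """Classify one aligned read under the quantification-window rules."""
    wstart, wend = ref.window
    left = ref.edge_exclusion_left
    right = len(ref.sequence) - ref.edge_exclusion_right
    cut = ref.cut_index
    in_window: list[tuple[str, int, int]] = []
    tokens: list[tuple[int, str]] = []
    templated = False

    exp = ref.expected_plus1_base
    run_start, run_end = cut, cut
    while run_start > 0 and ref.sequence[run_start - 1] == exp:
        run_start -= 1
    while run_end < len(ref.sequence) and ref.sequence[run_end] == exp:
        run_end += 1

    for gap, bases in alignment.insertions:
        if gap < left or gap > right:
            continue  # edge-excluded
        if wstart <= gap <= wend:
            in_window.append(("insertion", len(bases), gap))
            if len(bases) == 1 and bases == exp and run_start <= gap <= run_end:
                templated = True
                tokens.append((gap, f"+1{exp}@cut"))
            else:
                tokens.append((gap, f"+{len(bases)}{bases}@{_fmt_offset(gap - cut)}"))
    for dstart, dend in alignment.deletions:
        if dend <= left or dstart >= right:
            continue
        if dstart < wend and dend > wstart:  # interval overlap with window
            in_window.append(("deletion", dend - dstart, dstart))
            tokens.append((dstart, f"-{dend - dstart}@{_fmt_offset(dstart - cut)}"))
    n_subs = sum(1 for pos, _ in alignment.substitutions if left <= pos < right)

    if in_window:
        tokens.sort()
        return AlleleCall(
            read_id=read_id,
            status="modified",
            signature=";".join(t for _, t in tokens),
            in_window_indels=in_window,
            n_substitutions=n_subs,
            templated_plus1=templated,
        )
    return AlleleCall(read_id=read_id, status="unmodified", signature="WT",
                      n_substitutions=n_subs)


def quantify_reads(
    reads,
    ref: AmpliconReference,
    min_mean_q: float = 30.0,
    min_homology: float = 0.60,
) -> list[AlleleCall]:
    """Full per-read pipeline: quality filter, align, call."""
    calls: list[AlleleCall] = []
    for read in reads:
        if not quality_filter(read, min_mean_q):
            calls.append(AlleleCall(read.read_id, "discarded-quality"))
            continue
        aln = align_to_amplicon(read, ref, min_homology)
        if aln is None:
            calls.append(AlleleCall(read.read_id, "discarded-homology"))
            continue
        calls.append(call_edits(read.read_id, aln, ref))
    return calls


def tabulate(calls: list[AlleleCall]) -> AlleleFrequencyTable:
    """Aggregate allele calls into a frequency table.

    Frequencies are over retained reads; rows are ordered by descending
    count then signature.  An empty retained set yields a zero-total table
    with the undefined-percent flag set.
    """
    retained = [c for c in calls if c.status in ("unmodified", "modified")]
    discarded = len(calls) - len(retained)
    counts: dict[str, int] = {}
    for c in retained:
        counts[c.signature] = counts.get(c.signature, 0) + 1
    n = len(retained)
    rows = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["signature", "read_count"],
    )
    if n:
        rows["frequency"] = rows["read_count"] / n
        pct_mod = 100.0 * sum(1 for c in retained if c.status == "modified") / n
        pct_plus1 = 100.0 * sum(1 for c in retained if c.templated_plus1) / n
        return AlleleFrequencyTable(rows, n, discarded, pct_mod, pct_plus1)
    rows["frequency"] = pd.Series(dtype=float)
    return AlleleFrequencyTable(rows, 0, discarded, float("nan"), float("nan"),
                                percent_undefined=True)


# ---------------------------------------------------------------------------
# FASTQ I/O and paired-end merging

def read_fastq(path):
    """Yield SequencedRead from a (optionally gzipped) phred33 FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                return
            bases = fh.readline().strip().upper()
            fh.readline()
            quals = fh.readline().strip()
            yield SequencedRead(header[1:].split()[0], bases, quals)


def merge_exact_overlap(r1: SequencedRead, r2: SequencedRead,
                        min_overlap: int = 10) -> SequencedRead | None:
    """Merge a synthetic read pair by exact suffix/prefix overlap.

    ``r2`` is reverse-complemented first.  Returns None when no exact
    overlap of at least ``min_overlap`` bases exists.  This is a helper
    for simulated pairs, not a production merger.
    """
    b2 = revcomp(r2.bases)
    q2 = r2.quals[::-1]
    max_ov = min(len(r1.bases), len(b2))
    for ov in range(max_ov, min_overlap - 1, -1):
        if r1.bases[-ov:] == b2[:ov]:
            return SequencedRead(
                r1.read_id, r1.bases + b2[ov:], r1.quals + q2[ov:]
            )
    return None


def write_summary_json(table: AlleleFrequencyTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in table.summary().items()},
            fh, indent=2,
        )
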