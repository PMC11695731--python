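"""Coding-sequence model, HGVS-style variants, translation and RFLP digestion.

This module carries the substrate for reading-frame-rescue analysis: a coding
sequence with an exon table in 1-based HGVS c.-coordinates, delins application
and decomposition into atomic edits, translation with premature-stop location,
protein diffing, and in silico restriction digestion for PCR-RFLP genotyping.

Coordinate convention: all public interfaces use 1-based inclusive coding
positions (the HGVS ``c.`` convention, so ``c.4872_4876`` spans five bases);
internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

_NT = set("ACGT")

#: IUPAC nucleotide codes expanded to the concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """A variant's stated reference bases disagree with the coding model."""


@dataclass(frozen=True)
class CodingModel:
    """A coding sequence with exon intervals in c.-coordinates.

    ``exons`` is an ordered list of ``(label, start_c, end_c)`` 1-based
    inclusive intervals that jointly tile ``1..len(sequence)`` without gaps
    or overlaps.
    """

    id: str
    sequence: str
    exons: tuple[tuple[str, int, int], ...]
    # Set by apply_variant on derived (mutant) models: (shift_after_c, shift),
    # mapping the mutant's own c.-numbering back to reference positions.
    offset_map: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.sequence or len(self.sequence) < 3:
            raise ValueError("coding sequence must be at least one codon")
        if set(self.sequence) - _NT:
            raise ValueError("sequence must be uppercase ACGT")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        pos = 1
        for label, start, end in self.exons:
            if start != pos or end < start:
                raise ValueError(
                    f"exon {label!r} [{start},{end}] breaks contiguous "
                    f"c.-space coverage at position {pos}"
                )
            pos = end + 1
        if pos != len(self.sequence) + 1:
            raise ValueError("exons do not cover the full coding sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos_c: int) -> str:
        """Base at 1-based coding position ``pos_c``."""
        if not 1 <= pos_c <= len(self.sequence):
            raise IndexError(f"c.{pos_c} outside 1..{len(self.sequence)}")
        return self.sequence[pos_c - 1]

    def slice_c(self, start_c: int, end_c: int) -> str:
        """Bases of the 1-based inclusive interval [start_c, end_c]."""
        if not (1 <= start_c <= end_c <= len(self.sequence)):
            raise IndexError(f"c.{start_c}_{end_c} out of range")
        return self.sequence[start_c - 1 : end_c]

    def exon_of(self, pos_c: int) -> str:
        """Label of the exon containing coding position ``pos_c``."""
        for label, start, end in self.exons:
            if start <= pos_c <= end:
                return label
        raise IndexError(f"c.{pos_c} not covered by any exon")


@dataclass(frozen=True)
class DelinsVariant:
    """An HGVS-style delins: replace [start_c, end_c] (1-based, inclusive)
    by ``alt``.  Pure insertions are represented by anchoring on the base at
    ``start_c`` (ref is that base, alt is ref plus the inserted bases)."""

    start_c: int
    end_c: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.start_c > self.end_c or self.start_c < 1:
            raise ValueError("start_c must be >= 1 and <= end_c")
        if len(self.ref) != self.end_c - self.start_c + 1:
            raise ValueError("ref length must equal end_c - start_c + 1")
        if (set(self.ref) | set(self.alt)) - _NT:
            raise ValueError("ref/alt must be ACGT")

    @property
    def net_length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def inverse(self, model_after: "CodingModel") -> "DelinsVariant":
        """The variant that undoes this one on the edited model."""
        return DelinsVariant(
            start_c=self.start_c,
            end_c=self.start_c + len(self.alt) - 1,
            ref=self.alt,
            alt=self.ref,
        )


@dataclass(frozen=True)
class AtomicVariant:
    """A single-nucleotide deletion, insertion, or substitution in reference
    c.-coordinates.  Insertions are placed after ``position_c``."""

    kind: str  # deletion | insertion | substitution
    position_c: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.kind == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError("substitution needs distinct single ref/alt")
        elif self.kind == "deletion":
            if self.alt or len(self.ref) != 1:
                raise ValueError("deletion has single ref and empty alt")
        elif self.kind == "insertion":
            if self.ref or len(self.alt) != 1:
                raise ValueError("insertion has empty ref and single alt")
        else:
            raise ValueError(f"unknown atomic variant kind {self.kind!r}")


@dataclass
class ProteinDiff:
    """Residue-level comparison of two translated alleles."""

    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    frame_restored: bool = False
    premature_stop_exon: str | None = None
    identical_outside_region: bool | None = None

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as an IUPAC recognition pattern plus the cut
    offset within the site (forward strand)."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise ValueError("recognition site must be >= 4 nt")
        if set(self.recognition) - set(IUPAC):
            raise ValueError("recognition must be IUPAC nucleotide codes")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition site")


# Standard REBASE definitions; the allele assignment (BanII = humanized
# wild-type exon 44 allele, AvaII = founder-mutant allele) follows the
# PCR-RFLP genotyping scheme this package models.
BANII = RestrictionEnzyme("BanII", "GRGCYC", 5)
AVAII = RestrictionEnzyme("AvaII", "GGWCC", 1)


# ---------------------------------------------------------------------------
# variant application

def apply_variant(model: CodingModel, variant: DelinsVariant) -> CodingModel:
    """Realize a variant allele: replace [start_c, end_c] with alt.

    Exon boundaries downstream of the edit shift by the net length change;
    the returned model's ``offset_map`` records ``(shift_after_c, shift)``
    so mutant c.-positions beyond the edit map back to reference positions
    by adding ``-shift``.

    Raises ReferenceMismatchError if the variant's ref bases disagree with
    the model.
    """
    observed = model.slice_c(variant.start_c, variant.end_c)
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"variant ref {variant.ref!r} != model {observed!r} at "
            f"c.{variant.start_c}_{variant.end_c}"
        )
    shift = variant.net_length_change
    seq = (
        model.sequence[: variant.start_c - 1]
        + variant.alt
        + model.sequence[variant.end_c :]
    )
    new_exons = []
    for label, start, end in model.exons:
        if end < variant.start_c:
            new_exons.append((label, start, end))
        elif start > variant.end_c:
            new_exons.append((label, start + shift, end + shift))
        else:
            # exon containing (or straddling) the edit keeps its start and
            # absorbs the length change
            new_exons.append((label, start, end + shift if end >= variant.end_c else end))
    # drop exons emptied by a deletion, clamp ends
    cleaned = []
    pos = 1
    for label, start, end in new_exons:
        if end < start:
            continue
        cleaned.append((label, pos, pos + (end - start)))
        pos += end - start + 1
    return CodingModel(
        id=f"{model.id}|{variant.start_c}_{variant.end_c}delins{variant.alt}",
        sequence=seq,
        exons=tuple(cleaned),
        offset_map=(variant.start_c + len(variant.alt) - 1, shift),
    )


# ---------------------------------------------------------------------------
# delins decomposition

def decompose_delins(model: CodingModel, variant: DelinsVariant) -> list[AtomicVariant]:
    """Minimal atomic-edit decomposition of a delins, gaps placed 5'-most.

    Unit-cost dynamic programming over (ref, alt); among co-optimal edit
    scripts the traceback prefers substitutions/matches over gaps, which
    pushes indels to the 5' end of the interval.  Positions are reported in
    reference c.-coordinates.
    """
    observed = model.slice_c(variant.start_c, variant.end_c)
    if observed != variant.ref:
        raise ReferenceMismatchError("variant does not match model")
    ref, alt = variant.ref, variant.alt
    m, n = len(ref), len(alt)
    # d[i][j] = edit distance between ref[:i] and alt[:j]
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if ref[i - 1] == alt[j - 1] else 1
            d[i][j] = min(d[i - 1][j - 1] + cost, d[i - 1][j] + 1, d[i][j - 1] + 1)
    edits: list[AtomicVariant] = []
    i, j = m, n
    while i > 0 or j > 0:
        cost = 0 if (i > 0 and j > 0 and ref[i - 1] == alt[j - 1]) else 1
        if i > 0 and j > 0 and d[i][j] == d[i - 1][j - 1] + cost:
            if cost:
                edits.append(
                    AtomicVariant("substitution", variant.start_c + i - 1,
                                  ref[i - 1], alt[j - 1])
                )
            i, j = i - 1, j - 1
        elif i > 0 and d[i][j] == d[i - 1][j] + 1:
            edits.append(
                AtomicVariant("deletion", variant.start_c + i - 1, ref[i - 1], "")
            )
            i -= 1
        else:
            edits.append(
                AtomicVariant("insertion", variant.start_c + i - 1, "", alt[j - 1])
            )
            j -= 1
    edits.reverse()
    return edits


# ---------------------------------------------------------------------------
# translation and stop analysis

def translate(model: CodingModel) -> tuple[str, int | None]:
    """Translate from c.1 with the standard code.

    Returns ``(protein, stop_codon_index)``: the amino-acid string up to
    (excluding) the first stop codon, and that stop's 1-based codon index,
    or None if no stop codon occurs.  Trailing bases short of a codon are
    ignored.
    """
    n_codons = len(model.sequence) // 3
    if n_codons == 0:
        raise ValueError("sequence shorter than one codon")
    aa = str(Seq(model.sequence[: n_codons * 3]).translate())
    stop = aa.find("*")
    if stop == -1:
        return aa, None
    return aa[:stop], stop + 1


def frame_status(ref_model: CodingModel, alt_model: CodingModel) -> int:
    """Net length change mod 3; 0 means the reading frame is preserved."""
    return (len(alt_model.sequence) - len(ref_model.sequence)) % 3


def locate_premature_stop(model: CodingModel) -> str | None:
    """Exon label containing the first premature in-frame stop codon.

    A stop is premature when it is not the sequence's terminal codon.  A
    stop spanning an exon boundary is attributed to the exon containing
    its first base.  Returns None when the only stop is terminal (or no
    stop exists).
    """
    _, stop_idx = translate(model)
    if stop_idx is None:
        return None
    if stop_idx == len(model.sequence) // 3 and len(model.sequence) % 3 == 0:
        return None  # terminal stop
    first_base_c = (stop_idx - 1) * 3 + 1
    return model.exon_of(first_base_c)


def protein_diff(
    wt: str,
    edited: str,
    region: tuple[int, int] | None = None,
) -> ProteinDiff:
    """Residue-by-residue comparison of two amino-acid strings.

    When lengths are equal, all differing positions are listed (1-based)
    and ``frame_restored`` is True (equal-length proteins reach the same
    stop).  ``region`` is an optional 1-based inclusive residue interval;
    when given, ``identical_outside_region`` asserts that all differences
    are confined to it.
    """
    diff = ProteinDiff()
    if len(wt) == len(edited):
        diff.frame_restored = True
        diff.substitutions = [
            (i + 1, a, b) for i, (a, b) in enumerate(zip(wt, edited)) if a != b
        ]
    if region is not None:
        lo, hi = region
        diff.identical_outside_region = all(
            lo <= i <= hi for i, _, _ in diff.substitutions
        ) and len(wt) == len(edited)
    return diff


# ---------------------------------------------------------------------------
# restriction digestion / RFLP

def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping sites are all found
    return re.compile(f"(?=({''.join(parts)}))")


def cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based gap indices where the enzyme cuts (forward strand only)."""
    rx = _iupac_regex(enzyme.recognition)
    return sorted(m.start() + enzyme.cut_offset for m in rx.finditer(sequence))


def digest(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths after cutting at every recognition site.

    Matching is forward-strand on the amplicon as given, with IUPAC codes
    expanded; fragment lengths always sum to the input length.  Zero sites
    yield the uncut amplicon as a single fragment.
    """
    cuts = [c for c in cut_positions(sequence, enzyme) if 0 < c < len(sequence)]
    bounds = [0] + sorted(set(cuts)) + [len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def rflp_genotype(
    amplicons: str | list[str],
    alleleA_enzyme: RestrictionEnzyme = BANII,
    alleleB_enzyme: RestrictionEnzyme = AVAII,
) -> str:
    """Classify amplicon(s) by differential digestion.

    Returns ``"alleleA"`` if only the A enzyme cuts, ``"alleleB"`` if only
    the B enzyme cuts, ``"heterozygous-candidate"`` if both patterns are
    observed across the supplied amplicon(s), and ``"uninformative"`` if
    neither enzyme cuts.
    """
    if isinstance(amplicons, str):
        amplicons = [amplicons]
    cuts_a = any(len(digest(a, alleleA_enzyme)) > 1 for a in amplicons)
    cuts_b = any(len(digest(a, alleleB_enzyme)) > 1 for a in amplicons)
    if cuts_a and cuts_b:
        return "heterozygous-candidate"
    if cuts_a:
        return "alleleA"
    if cuts_b:
        return "alleleB"
    return "uninformative"


# ---------------------------------------------------------------------------
# HGVS-c subset parsing and model I/O

_HGVS_PATTERNS = [
    ("delins", re.compile(r"^c\.(\d+)_(\d+)delins([ACGT]+)$")),
    ("del_range", re.compile(r"^c\.(\d+)_(\d+)del([ACGT]*)$")),
    ("del", re.compile(r"^c\.(\d+)del([ACGT]?)$")),
    ("sub", re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")),
    ("ins", re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")),
]


def parse_hgvs_c(text: str, model: CodingModel) -> DelinsVariant:
    """Parse a minimal HGVS-c subset against a coding model.

    Accepted forms: ``c.N_MdelinsXXX``, ``c.NdelX``, ``c.N_Mdel``,
    ``c.NX>Y``, ``c.N_MinsXXX`` (M must be N+1 for insertions).
    """
    text = text.strip()
    for kind, rx in _HGVS_PATTERNS:
        m = rx.match(text)
        if not m:
            continue
        if kind == "delins":
            start, end, alt = int(m.group(1)), int(m.group(2)), m.group(3)
            return DelinsVariant(start, end, model.slice_c(start, end), alt)
        if kind == "del_range":
            start, end = int(m.group(1)), int(m.group(2))
            ref = model.slice_c(start, end)
            stated = m.group(3)
            if stated and stated != ref:
                raise ReferenceMismatchError(f"{text}: ref is {ref}")
            # anchor on the preceding base so alt stays non-empty
            if start > 1:
                anchor = model.base(start - 1)
                return DelinsVariant(start - 1, end, anchor + ref, anchor)
            return DelinsVariant(start, end + 1, ref + model.base(end + 1),
                                 model.base(end + 1))
        if kind == "del":
            pos = int(m.group(1))
            ref = model.base(pos)
            if m.group(2) and m.group(2) != ref:
                raise ReferenceMismatchError(f"{text}: ref is {ref}")
            if pos > 1:
                anchor = model.base(pos - 1)
                return DelinsVariant(pos - 1, pos, anchor + ref, anchor)
            return DelinsVariant(pos, pos + 1, ref + model.base(pos + 1),
                                 model.base(pos + 1))
        if kind == "sub":
            pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
            if model.base(pos) != ref:
                raise ReferenceMismatchError(f"{text}: ref is {model.base(pos)}")
            return DelinsVariant(pos, pos, ref, alt)
        if kind == "ins":
            start, end, ins = int(m.group(1)), int(m.group(2)), m.group(3)
            if end != start + 1:
                raise ValueError(f"{text}: insertion must be between adjacent bases")
            ref = model.base(start)
            return DelinsVariant(start, start, ref, ref + ins)
    raise ValueError(f"unsupported HGVS expression: {text!r}")


def read_coding_model(fasta_path, exons_tsv_path, model_id: str | None = None) -> CodingModel:
    """Load a CodingModel from a FASTA file plus a 3-column exon TSV
    (label, start_c, end_c)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    exons = []
    with open(exons_tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, start, end = line.split("\t")[:3]
            exons.append((label, int(start), int(end)))
    return CodingModel(
        id=model_id or record.id,
        sequence=str(record.seq).upper(),
        exons=tuple(exons),
    )


def write_coding_model(model: CodingModel, fasta_path, exons_tsv_path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{model.id}\n")
        for i in range(0, len(model.sequence), 70):
            fh.write(model.sequence[i : i + 70] + "\n")
    with open(exons_tsv_path, "w") as fh:
        for label, start, end in model.exons:
            fh.write(f"{label}\t{start}\t{end}\n")
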