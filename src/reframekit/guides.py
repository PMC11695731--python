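"""Mutation-specific protospacer enumeration and templated +1 prediction.

SpCas9 geometry used throughout: a 20-nt protospacer followed by an NGG PAM;
the blunt double-strand break falls between protospacer positions 17 and 18
(3 nt 5' of the PAM).  The staggered-cut repair model duplicates the base at
protospacer position 17 (the 4th base 5' of the PAM), producing a templated
+1 insertion at the cut.  For minus-strand guides the duplicated nucleotide
is reported on the allele (plus) strand, i.e. as the complement of the
guide-orientation base, so that ``indel_label`` matches what amplicon
sequencing of the allele would show.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .coding import (
    CodingModel,
    DelinsVariant,
    ProteinDiff,
    apply_variant,
    locate_premature_stop,
    protein_diff,
    revcomp,
    translate,
)

PAM_FWD = re.compile(r"(?=([ACGT]GG))")
PAM_REV = re.compile(r"(?=(CC[ACGT]))")  # NGG on the minus strand


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM hit on a given allele.

    ``protospacer_start`` is the 0-based half-open start of the 20-mer on
    the allele's plus strand regardless of guide strand; ``cut_position``
    is the 0-based gap index of the blunt cut (between protospacer
    positions 17|18 in guide orientation).
    """

    spacer: str  # 5'->3' in guide orientation
    pam: str
    strand: str  # '+' or '-'
    protospacer_start: int
    cut_position: int

    def __post_init__(self):
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if not re.fullmatch(r"[ACGT]GG", self.pam):
            raise ValueError("PAM must match NGG")
        expected = (
            self.protospacer_start + 17
            if self.strand == "+"
            else self.protospacer_start + 3
        )
        if self.cut_position != expected:
            raise ValueError("cut_position inconsistent with protospacer_start")


@dataclass(frozen=True)
class SpecificityCall:
    matches_mutant: bool
    matches_wildtype: bool
    best_wildtype_mismatches: int

    @property
    def mutant_specific(self) -> bool:
        return self.matches_mutant and not self.matches_wildtype


@dataclass
class EditPrediction:
    """Predicted templated +1 insertion outcome for one guide candidate."""

    duplicated_base: str  # on the allele (plus) strand
    predicted_allele: str
    indel_label: str  # "+1X"
    cut_position: int
    # 3'-most (HGVS-normalized) 1-based position after which the insertion
    # is reported; the mechanistic coordinate is cut_position.
    hgvs_position: int = 0
    reframe: ProteinDiff | None = None


def enumerate_protospacers(allele: str) -> list[GuideCandidate]:
    """All 20-mers followed by NGG on either strand, ordered by position
    then strand ('+' before '-')."""
    allele = allele.upper()
    out: list[GuideCandidate] = []
    if len(allele) < 23:
        return out
    for m in PAM_FWD.finditer(allele):
        p = m.start() - 20
        if p < 0:
            continue
        out.append(
            GuideCandidate(
                spacer=allele[p : p + 20],
                pam=m.group(1),
                strand="+",
                protospacer_start=p,
                cut_position=p + 17,
            )
        )
    for m in PAM_REV.finditer(allele):
        q = m.start()
        if q + 23 > len(allele):
            continue
        out.append(
            GuideCandidate(
                spacer=revcomp(allele[q + 3 : q + 23]),
                pam=revcomp(m.group(1)),
                strand="-",
                protospacer_start=q + 3,
                cut_position=q + 6,
            )
        )
    out.sort(key=lambda c: (c.protospacer_start, c.strand))
    return out


def _site_in_allele(spacer: str, allele: str) -> bool:
    """Exact spacer+NGG occurrence on either strand of ``allele``."""
    target = re.compile(re.escape(spacer) + r"[ACGT]GG")
    return bool(target.search(allele)) or bool(target.search(revcomp(allele)))


def allele_specificity(
    candidate: GuideCandidate, wt_allele: str, mut_allele: str
) -> SpecificityCall:
    """Binary allele specificity plus the best wild-type mismatch count.

    ``matches_wildtype`` is True iff the exact spacer with an NGG occurs in
    the wild-type allele (either strand).  ``best_wildtype_mismatches`` is
    the minimum Hamming distance between the spacer and any NGG-adjacent
    wild-type 20-mer (20 when the wild type has no NGG site at all).
    """
    wt_allele, mut_allele = wt_allele.upper(), mut_allele.upper()
    best = 20
    for cand in enumerate_protospacers(wt_allele):
        mm = sum(a != b for a, b in zip(candidate.spacer, cand.spacer))
        best = min(best, mm)
    return SpecificityCall(
        matches_mutant=_site_in_allele(candidate.spacer, mut_allele),
        matches_wildtype=_site_in_allele(candidate.spacer, wt_allele),
        best_wildtype_mismatches=best,
    )


def predict_templated_insertion(
    candidate: GuideCandidate, allele: str
) -> EditPrediction:
    """Apply the staggered-cut duplication rule to one candidate.

    The duplicated nucleotide is the allele base templating the 1-nt 5'
    overhang fill-in: ``allele[cut-1]`` for plus-strand guides and
    ``allele[cut]`` for minus-strand guides (both equal the guide-strand
    base at protospacer position 17, read on the plus strand).
    """
    allele = allele.upper()
    cut = candidate.cut_position
    base = allele[cut - 1] if candidate.strand == "+" else allele[cut]
    predicted = allele[: cut] + base + allele[cut:]
    # HGVS 3'-most normalization: slide right through the homopolymer run
    pos = cut
    while pos < len(allele) and allele[pos] == base:
        pos += 1
    return EditPrediction(
        duplicated_base=base,
        predicted_allele=predicted,
        indel_label=f"+1{base}",
        cut_position=cut,
        hgvs_position=pos,  # insertion reported after this many bases (1-based anchor)
    )


def evaluate_reframe(
    prediction: EditPrediction,
    wt_model: CodingModel,
    mut_model: CodingModel,
) -> ProteinDiff:
    """Translate wild type and the predicted post-repair allele and diff.

    ``frame_restored`` requires equal protein length; the predicted
    allele's first premature stop exon (if any) is reported on the mutant
    model's exon structure shifted by the insertion.
    """
    cut = prediction.cut_position
    if cut >= 1:
        ins_var = DelinsVariant(
            start_c=cut,
            end_c=cut,
            ref=mut_model.sequence[cut - 1],
            alt=mut_model.sequence[cut - 1] + prediction.duplicated_base,
        )
    else:  # cut at the very start: anchor on the first base
        ins_var = DelinsVariant(1, 1, mut_model.sequence[0],
                                prediction.duplicated_base + mut_model.sequence[0])
    predicted_model = apply_variant(mut_model, ins_var)
    assert predicted_model.sequence == prediction.predicted_allele
    wt_aa, wt_stop = translate(wt_model)
    pred_aa, pred_stop = translate(predicted_model)
    diff = protein_diff(wt_aa, pred_aa)
    diff.frame_restored = len(wt_aa) == len(pred_aa) and wt_stop == pred_stop
    diff.premature_stop_exon = locate_premature_stop(predicted_model)
    return diff


@dataclass
class RankedGuide:
    candidate: GuideCandidate
    specificity: SpecificityCall
    prediction: EditPrediction
    reframe: ProteinDiff | None = None


def rank_guides(
    entries: list[RankedGuide], variant_position: int | None = None
) -> list[RankedGuide]:
    """Deterministic design ranking.

    Order: mutant-specific first, then frame-restoring predictions, then
    fewer predicted premature stops, then cut-site distance from the
    variant (when a variant position is given), ties broken by protospacer
    position then strand.
    """

    def key(e: RankedGuide):
        frame_ok = bool(e.reframe and e.reframe.frame_restored)
        n_stops = int(bool(e.reframe and e.reframe.premature_stop_exon))
        dist = (
            abs(e.candidate.cut_position - variant_position)
            if variant_position is not None
            else 0
        )
        return (
            not e.specificity.mutant_specific,
            not frame_ok,
            n_stops,
            dist,
            e.candidate.protospacer_start,
            e.candidate.strand,
        )

    return sorted(entries, key=key)


def design_report_rows(ranked: list[RankedGuide]) -> list[dict]:
    """Flatten a ranked design report for TSV/JSON output."""
    rows = []
    for e in ranked:
        rows.append(
            {
                "spacer": e.candidate.spacer,
                "pam": e.candidate.pam,
                "strand": e.candidate.strand,
                "cut_position": e.candidate.cut_position,
                "mutant_specific": e.specificity.mutant_specific,
                "best_wt_mismatches": e.specificity.best_wildtype_mismatches,
                "predicted_indel": e.prediction.indel_label,
                "frame_restored": bool(e.reframe and e.reframe.frame_restored),
                "n_substitutions": e.reframe.n_substitutions if e.reframe else None,
                "premature_stop_exon": e.reframe.premature_stop_exon if e.reframe else None,
            }
        )
    return rows


def write_design_report(ranked: list[RankedGuide], tsv_path=None, json_path=None):
    rows = design_report_rows(ranked)
    if tsv_path:
        import pandas as pd

        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2)
    return rows
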