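"""Single-cell clone genotyping tallies.

After editing, single cell-derived clones are expanded and both alleles of
each clone are genotyped by subcloned-amplicon sequencing.  This module
turns per-clone allele signatures into the summary statistics reported for
such screens: the edited-clone distribution (unedited / heterozygous /
homozygous) and the share of edited alleles carrying a given indel
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

WT = "WT"


@dataclass(frozen=True)
class CloneGenotype:
    """Allele signatures of one diploid clone ('WT' = unedited allele)."""

    clone_id: str
    allele1: str
    allele2: str

    @property
    def n_edited_alleles(self) -> int:
        return (self.allele1 != WT) + (self.allele2 != WT)

    @property
    def category(self) -> str:
        n = self.n_edited_alleles
        return ("unedited", "heterozygous", "homozygous")[n]


def clone_table_from_counts(
    n_clones: int,
    n_edited_clones: int,
    n_edited_alleles: int,
    n_signature_alleles: int,
    signature: str = "+1A",
    other_signature: str = "other-indel",
) -> list[CloneGenotype]:
    """Reconstruct a minimal clone table from aggregate screen counts.

    The homozygous/heterozygous split follows uniquely from the totals:
    ``n_hom = n_edited_alleles - n_edited_clones`` and
    ``n_het = n_edited_clones - n_hom``.  Alleles carrying ``signature``
    are assigned to homozygous clones first; remaining edited alleles get
    ``other_signature``.
    """
    n_hom = n_edited_alleles - n_edited_clones
    n_het = n_edited_clones - n_hom
    n_unedited = n_clones - n_edited_clones
    if min(n_hom, n_het, n_unedited) < 0:
        raise ValueError("inconsistent clone counts")
    if not 0 <= n_signature_alleles <= n_edited_alleles:
        raise ValueError("signature allele count out of range")
    sig_left = n_signature_alleles
    clones: list[CloneGenotype] = []
    idx = 1

    def take() -> str:
        nonlocal sig_left
        if sig_left > 0:
            sig_left -= 1
            return signature
        return other_signature

    for _ in range(n_hom):
        clones.append(CloneGenotype(f"clone{idx:02d}", take(), take()))
        idx += 1
    for _ in range(n_het):
        clones.append(CloneGenotype(f"clone{idx:02d}", take(), WT))
        idx += 1
    for _ in range(n_unedited):
        clones.append(CloneGenotype(f"clone{idx:02d}", WT, WT))
        idx += 1
    return clones


def edited_allele_summary(clones: list[CloneGenotype], signature: str = "+1A") -> dict:
    """Tally edited clones/alleles and the share carrying ``signature``."""
    alleles = [a for c in clones for a in (c.allele1, c.allele2)]
    edited = [a for a in alleles if a != WT]
    n_sig = sum(1 for a in edited if a == signature)
    categories = {"unedited": 0, "heterozygous": 0, "homozygous": 0}
    for c in clones:
        categories[c.category] += 1
    return {
        "n_clones": len(clones),
        "n_edited_clones": categories["heterozygous"] + categories["homozygous"],
        "categories": categories,
        "n_edited_alleles": len(edited),
        "n_signature_alleles": n_sig,
        "percent_signature_of_edited": (
            100.0 * n_sig / len(edited) if edited else float("nan")
        ),
    }
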