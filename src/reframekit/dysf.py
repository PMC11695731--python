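"""Synthetic DYSF-exon-44-like coding model (constraint-derived fixture).

This module builds a *synthetic* stand-in for the human dysferlin (*DYSF*)
coding sequence around exon 44.  The true transcript is not bundled; instead
the model is reconstructed from the published constraints on the founder
frameshift allele, which determine the local sequence essentially uniquely:

* the exon 44 founder lesion is ``c.4872_4876delinsCCCC``, decomposing into
  a G deletion at c.4872 plus a G>C exchange at c.4876 — so the reference
  pentamer at c.4872_4876 is ``GCCCG``;
* c.-numbering ties codon 1622 to c.4864–4866;
* the templated +1A repair of the mutant allele exchanges exactly four
  residues (T1622N, L1623A, E1624G, V1626L) while Pro1625 is untouched.

Working through the genetic code, those facts force codons 1620–1626 to be
``CCA GCA ACG CTG GAG CCC GTC`` with the Cas9 cut at the codon 1621/1622
junction templated from a minus-strand NGG protospacer (PAM complement
``CCA`` at c.4858–4860).  Everything outside this window — overall length
(6243 nt, 2080 residues, matching dysferlin's size), exon boundaries, and
flanking sequence — is synthetic: random stop-free codons from a fixed
generator, an exon 44 spanning c.4801–4886 and exon 45 spanning
c.4887–5000.  Downstream codons are fixed so that the mutant allele's
shifted reading frame runs stop-free through the remainder of exon 44 and
terminates at a premature stop early in exon 45, mirroring the reported
consequence of the founder frameshift.
"""

from __future__ import annotations

import numpy as np

from .coding import CodingModel, DelinsVariant, apply_variant

#: HGVS description of the founder lesion modelled here.
FOUNDER_HGVS = "c.4872_4876delinsCCCC"

N_RESIDUES = 2080  # dysferlin-sized protein
_N_CODONS = N_RESIDUES + 1  # incl. terminal stop

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS
)

# 1-based codon -> fixed codon.  1620 supplies the minus-strand PAM (CCA),
# 1621 ends in the templated A, 1622-1626 encode T-L-E-P-V with the exact
# nucleotides forced by the delins and the four residue exchanges, and
# 1627-1631 are chosen so the frameshifted mutant allele reads
# ...GAC CCC TCG CTG CTG CTC TGA: stop-free within exon 44 and terminating
# at a TGA whose first base lies in exon 45.
_FIXED_CODONS = {
    1620: "CCA",
    1621: "GCA",
    1622: "ACG",  # Thr1622
    1623: "CTG",  # Leu1623
    1624: "GAG",  # Glu1624  (3rd base = c.4872, the deleted G)
    1625: "CCC",  # Pro1625  (unchanged by reframing)
    1626: "GTC",  # Val1626  (1st base = c.4876, the G>C exchange)
    1627: "GCT",
    1628: "GCT",
    1629: "GCT",
    1630: "CTG",
    1631: "AAA",
}

_EXON44 = (4801, 4886)
_EXON45 = (4887, 5000)
_N_EXONS = 55

# Fixed generator: the model is a reference fixture, identical in every run.
_FIXTURE_SEED = 75923  # after the dysferlin protein accession digits


def _exon_table(total_len: int) -> tuple[tuple[str, int, int], ...]:
    exons: list[tuple[str, int, int]] = []
    # exons 1..43 tile 1..4800
    pos = 1
    n_front, front_end = 43, _EXON44[0] - 1
    size = front_end // n_front
    for i in range(1, n_front + 1):
        end = front_end if i == n_front else pos + size - 1
        exons.append((str(i), pos, end))
        pos = end + 1
    exons.append(("44", *_EXON44))
    exons.append(("45", *_EXON45))
    pos = _EXON45[1] + 1
    n_back = _N_EXONS - 45
    back_len = total_len - pos + 1
    size = back_len // n_back
    for i in range(46, _N_EXONS + 1):
        end = total_len if i == _N_EXONS else pos + size - 1
        exons.append((str(i), pos, end))
        pos = end + 1
    return tuple(exons)


def dysf_exon44_model() -> CodingModel:
    """The synthetic wild-type DYSF-like coding model (deterministic)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    codons = ["ATG"]
    codons += [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS),
                                                      _N_CODONS - 2)]
    codons.append("TGA")
    for codon_number, codon in _FIXED_CODONS.items():
        codons[codon_number - 1] = codon
    seq = "".join(codons)
    return CodingModel(
        id="DYSF_ex44_synthetic",
        sequence=seq,
        exons=_exon_table(len(seq)),
    )


def founder_variant(model: CodingModel | None = None) -> DelinsVariant:
    """The exon 44 founder delins on the synthetic model (GCCCG -> CCCC)."""
    model = model or dysf_exon44_model()
    return DelinsVariant(4872, 4876, model.slice_c(4872, 4876), "CCCC")


def mutant_model(model: CodingModel | None = None) -> CodingModel:
    """The founder-mutant allele realized on the synthetic model."""
    model = model or dysf_exon44_model()
    return apply_variant(model, founder_variant(model))


def design_window(margin: int = 110) -> tuple[str, str, int]:
    """Matched wild-type / mutant sequence windows around the lesion.

    Returns ``(wt_window, mut_window, window_start_c)`` where both windows
    start at the same reference coding position (1-based).  Guide design on
    the full >6 kb model is unnecessary; the screen operates on the exon 44
    amplicon context, as a targeted assay would.
    """
    wt = dysf_exon44_model()
    mut = mutant_model(wt)
    start_c = 4872 - margin
    end_c = 4876 + margin
    return (
        wt.slice_c(start_c, end_c),
        mut.slice_c(start_c, end_c - 1),  # mutant is 1 nt shorter
        start_c,
    )
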