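# reframekit

Tools for rescuing frameshift alleles by CRISPR-Cas9 templated +1
insertion: mutation-specific guide design with repair-outcome prediction,
amplicon deep-sequencing quantification of editing outcomes, and GUIDE-seq
off-target site calling — with seeded synthetic-data generators so every
stage is testable end-to-end without external downloads.

## The problem

Loss-of-function frameshifts, such as the *DYSF* exon 44 founder mutation
c.4872_4876delinsCCCC behind a form of limb-girdle muscular dystrophy
(dysferlinopathy), truncate the protein through a premature stop codon.
When Cas9 cleaves with a staggered end, fill-in of the 1-nt 5′ overhang
duplicates the fourth base 5′ of the PAM — a predictable +1 insertion. At
a net −1 frameshift lesion, a guide whose cut templates the right +1
insertion restores the reading frame in place, without skipping the exon;
the price is a handful of residue exchanges around the lesion (here
T1622N, L1623A, E1624G, V1626L). `reframekit` implements the full
computational chain around that strategy:

- **`reframekit.coding`** — coding-sequence model with HGVS c.-coordinates
  and exon structure, delins application and minimal decomposition into
  atomic edits, translation with premature-stop location, protein diffing,
  and in-silico restriction digestion for PCR-RFLP genotyping
  (BanII/AvaII allele discrimination).
- **`reframekit.guides`** — NGG protospacer enumeration on both strands,
  mutant-vs-wild-type allele specificity, the staggered-cut +1 duplication
  prediction, reframing evaluation, and deterministic guide ranking.
- **`reframekit.amplicon`** — per-read quality filtering (mean phred
  > 30), affine-gap alignment to the amplicon (60% homology floor), a
  30-bp quantification window at the cut with 15-bp edge exclusion, and
  allele-frequency tables with templated-+1 and percent-modified
  summaries.
- **`reframekit.guideseq`** — per-sample overlap clustering of aligned
  tag-integration records, cross-sample intersection, the 200-read /
  ≥2-sample / control-negative filter chain with allowlist rescue,
  ≤4-mismatch off-target enumeration with PAM-proximity-weighted scoring,
  top-10-plus-exonic validation selection, and prediction intersection.
- **`reframekit.simulate`** — seeded generators for every input: coding
  fixtures with frameshift lesions, amplicon FASTQ with programmed allele
  spectra, toy genomes with planted off-target sites, and GUIDE-seq
  record tables with true sites, decoys, and background.
- **`reframekit.dysf`** — a synthetic dysferlin-exon-44-like coding model
  reconstructed from the published constraints on the founder allele (see
  `docs/methods.md` for the derivation and its limits).

## Worked example

Design mutation-specific guides for the founder delins on the synthetic
exon 44 model and evaluate the predicted repair:

```python
from reframekit.coding import decompose_delins, locate_premature_stop
from reframekit.dysf import dysf_exon44_model, founder_variant, mutant_model, design_window
from reframekit.guides import (enumerate_protospacers, allele_specificity,
                               predict_templated_insertion)

wt = dysf_exon44_model()
var = founder_variant(wt)
for a in decompose_delins(wt, var):
    print(f"{a.kind} at c.{a.position_c}: {a.ref or '-'}>{a.alt or '-'}")
print("premature stop exon:", locate_premature_stop(mutant_model(wt)))

wt_win, mut_win, start_c = design_window()
for c in enumerate_protospacers(mut_win):
    if allele_specificity(c, wt_win, mut_win).mutant_specific:
        p = predict_templated_insertion(c, mut_win)
        print(f"{c.spacer} ({c.strand}) cut@c.{start_c + c.cut_position - 1}"
              f"|{start_c + c.cut_position}: predicted {p.indel_label}")
```

prints

```
deletion at c.4872: G>-
substitution at c.4876: G>C
premature stop exon: 45
AGCGAGGGGTCCAGCGTTGC (-) cut@c.4863|4864: predicted +1A
AGTTTCAGAGCAGCAGCGAG (-) cut@c.4877|4878: predicted +1G
GTAGTTTCAGAGCAGCAGCG (-) cut@c.4879|4880: predicted +1T
```

The delins splits into a single-base deletion (the frameshift) plus a
benign exchange; the frameshift lands a premature stop in exon 45. Three
guides match only the mutant allele, and exactly one of them — cutting at
the codon 1621/1622 junction — templates a +1A, the insertion that
restores the frame. Evaluating that prediction
(`guides.evaluate_reframe`) confirms frame restoration with exactly four
residue exchanges, T1622N / L1623A / E1624G / V1626L, and no premature
stop.

The same flows are scriptable from the shell:

```sh
reframekit design wt.fasta exons.tsv "c.4872_4876delinsCCCC" --out-json design.json
reframekit quantify reads.fastq.gz amplicon.fasta --spacer AGCGAGGGGTCCAGCGTTGC
reframekit guideseq records.tsv --genome-fasta genome.fa --spacer ... --allowlist-bed allow.bed
reframekit simulate dataset.yaml out/   # seeded synthetic dataset + manifest
```

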