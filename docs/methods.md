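# Methods

`reframekit` models the computational chain around rescuing a frameshifted
exon by a templated single-base insertion: allele-specific guide design
with outcome prediction, amplicon-sequencing quantification of editing
outcomes, and GUIDE-seq-style off-target site calling. This note records
the models, parameter choices, numerical conventions, and what the
synthetic data do and do not establish.

## The reframing model

SpCas9 guided by a 20-nt spacer cleaves 3 bp 5′ of an NGG PAM (between
protospacer positions 17 and 18). At many sites cleavage is staggered,
leaving a 1-nt 5′ overhang whose fill-in and ligation duplicate the base at
protospacer position 17 — the fourth base 5′ of the PAM. The package treats
this as a deterministic prediction: for a candidate guide on an allele, the
predicted repair product is the allele with that base duplicated at the cut
(`guides.predict_templated_insertion`). For minus-strand guides the
duplicated nucleotide is reported on the coding (plus) strand, i.e. as the
complement of the guide-orientation base, so labels like `+1A` match what
amplicon sequencing of the locus shows. The mechanistic insertion
coordinate (the cut) is retained alongside the HGVS-normalised 3′-most
position, since duplicating a base inside a homopolymer makes the position
ambiguous.

A frameshift lesion with net length change of −1 (mod 3) is rescued by any
+1 insertion; the biology of the specific locus determines which inserted
base and hence which residue exchanges result. `guides.evaluate_reframe`
translates the wild-type and predicted alleles and reports frame
restoration, residue substitutions, and premature-stop status.

Guide ranking (`guides.rank_guides`) is a lexicographic order: allele
specificity first, then predicted frame restoration, then absence of
predicted premature stops, then cut-site distance from the variant, with
position/strand as the final tie-break. Specificity is binary — the exact
spacer with an NGG occurs in the mutant but not the wild-type allele — with
the best wild-type mismatch count reported but not thresholded. NAG PAMs
are ignored for design and available only in off-target scanning.

## The synthetic dysferlin exon 44 model

The package's worked example is the *DYSF* exon 44 founder frameshift
c.4872_4876delinsCCCC. The true transcript is not bundled;
`reframekit.dysf` instead constructs a synthetic dysferlin-sized coding
model (6243 nt, 2080 residues) whose local sequence is forced by the
published constraints, which pin it essentially uniquely:

* the delins decomposes into a G deletion at c.4872 plus a G>C exchange at
  c.4876, so the reference pentamer at c.4872–4876 is `GCCCG`;
* c.-numbering ties codon 1622 to c.4864–4866;
* templated +1A repair of the mutant allele exchanges exactly
  T1622N, L1623A, E1624G and V1626L while Pro1625 is untouched.

Working these through the genetic code forces codons 1620–1626 to
`CCA GCA ACG CTG GAG CCC GTC`, a minus-strand NGG protospacer with its cut
at the codon 1621/1622 junction, and `A` as the templated base. Everything
outside this window — flanking sequence (stop-free random codons from a
fixed generator), the exon tiling (55 exons; exon 44 at c.4801–4886,
exon 45 at c.4887–5000) — is synthetic. Downstream codons are fixed so the
frameshifted mutant reads stop-free through the rest of exon 44 and
terminates early in exon 45, reproducing the premature-stop placement. The
consequence: decomposition positions, the four residue exchanges, and the
premature-stop exon are *derived by the code* from this model, but the
exon-boundary placement itself is a construction, not a measurement.

## Amplicon editing-outcome quantification

Per read: (1) keep iff mean phred33 quality is strictly greater than 30
(no per-base masking); (2) align globally to the amplicon under affine
scoring — match +2, mismatch −4, gap open −10, gap extend −1 — with free
end gaps on the reference side only, so a read may cover part of the
amplicon but must itself align end-to-end (otherwise a random read could
hide behind free end gaps and appear locally perfect); both orientations
are tried and the higher-scoring one kept; (3) discard when identity over
the aligned columns (matches / columns between the first and last aligned
pair, internal gap columns included) is below 60%.

Windowing: the quantification window is `window_size` (default 30) bases
wide, centred on the sgRNA 3′ end offset by −3 — which is exactly the
blunt-cut gap index on either strand; odd sizes round the left half down.
15 bp at each amplicon edge are excluded: indels falling entirely inside an
edge zone are ignored, as are substitutions there. A read is *modified* iff
at least one indel overlaps the window (insertions compare their gap index
against the closed window bounds; deletions by interval overlap).
Substitutions are counted per read but never set modified status; the
package reports them separately because the question of whether
substitution-only reads count as edited is convention-dependent.

Indels are left-normalised against the reference before signature
assignment. A 1-bp insertion is labelled as the templated `+1X` event when
its base equals the expected duplicated base and its normalised position
falls within the homopolymer run of that base abutting the cut — the run
matters because inserting a base next to an identical base makes the gap
position degenerate.

Known measurement property: a substitution error landing on (or adjacent
to) the inserted base changes the observed allele, so at a per-base error
rate ε the templated-insertion class loses roughly ε × (a few positions)
of its mass to neighbouring signatures. At ε = 0.005 this is several
tenths of a percentage point — visible in the recovery checks, and exactly
zero at ε = 0.

## GUIDE-seq downstream analysis

The pipeline ingests aligned tag-integration records (BED-like TSV:
chrom, start, end, strand, sample, group), never raw reads — read mapping
is upstream of the artifact. Per sample, records on a chromosome are
clustered as connected components under ≥1 bp interval overlap (half-open;
touching intervals do not overlap). Each cluster's tag-integration
position is the modal strand-aware 5′ read end (start for +, end for −),
ties resolved to the smaller coordinate.

Clusters from all samples are intersected: integration positions on one
chromosome within 10 bp (single-linkage chaining) merge into one candidate
site. Filtering then applies, in this order of logic:

1. **Read cutoff before positivity.** A sample is *positive* at a site
   only if its member cluster carries ≥ 200 reads; a stray background read
   does not make a sample positive. This ordering (cutoff first, then
   replication) follows the stated procedure and is what makes decoy
   rejection exact.
2. **Replication.** ≥ 2 positive samples within the GSP+ group or within
   the GSP− group (either primer orientation suffices; a strict mode
   requiring a specific group is a parameter away via `group_sum`).
3. **Control negativity.** No control sample may show a cluster of ≥ 2
   reads at the site. The threshold of 2 resolves an otherwise unstated
   convention: a single tag read in a control is expected under the
   uniform background model and is not a detection.
4. **Allowlist.** An allowlisted interval (matched against the integration
   position) waives the replication requirement only — the documented
   single-sample cluster still needs read support and clean controls.

Retained sites are intersected with mismatch-enumerated predictions: every
NGG-adjacent 20-mer on either strand within 4 mismatches of the spacer,
each scored as a product of positional weights `(21 − p)/21` over mismatch
positions p (1 = PAM-distal), so PAM-proximal mismatches penalise more.
This monotone surrogate preserves ranking semantics without claiming any
published weight table. Validation selection takes the top 10 by score
(ties by mismatch count, then coordinate) union all exonic predictions.
Sites are matched to the nearest predicted cut within 25 bp (ties to the
smaller coordinate); with predictions supplied, unpredicted sites are
dropped from the final report, mirroring the GUIDE-seq ∩ prediction
intersection. Cross-sample tolerance (10 bp) and prediction tolerance
(25 bp) are read-end-jitter-scale defaults, exposed in `FilterParams`.

## Synthetic data: what it emulates, what it does not

Generators are seeded `numpy` streams (one independent SHA-derived
substream per generator), so outputs are byte-reproducible per seed.

* **Amplicon reads**: drawn multinomially from a programmed allele
  spectrum, default 62% templated +1A, 20% −4 deletion, 10% other indel,
  8% unedited — i.e. >90% total editing with >60% templated insertions,
  the regime the package models — at n = 10,000 reads, substitution errors
  at 0.005/base, Gaussian phred33 qualities (mean 37, sd 2, clipped to
  [2, 41]). Reads are single-end and cover the whole amplicon; an
  exact-overlap merger is provided for synthetic pairs. Not emulated:
  quality-by-cycle decay, context-dependent or indel sequencing errors,
  PCR duplicates, chimeras. Recovery tests therefore establish the
  correctness of the windowing/alignment logic, not robustness to real
  sequencer artifacts.
* **Toy genomes**: random chromosomes (default 4 × 20 kb) with
  NGG-adjacent sites planted at prescribed mismatch counts; a rejection
  step redraws any chromosome carrying an accidental extra hit within the
  scan threshold, so the planted truth table is exhaustive.
* **GUIDE-seq records**: per planted site and participating sample, read
  counts are Poisson around the site mean (default 300 for true sites),
  intervals jittered (sd 3 bp) around the integration position on both
  strands; control-contaminated plants emit control records at half the
  mean; uniform background singletons (20 records/sample) exercise the
  filters. Poisson support and uniform background are the simplest models
  that exercise every rule; real tag-integration libraries have structured
  backgrounds these do not represent.
* **The validation plan** (`simulate.guideseq_validation_plan`): seven
  filter-passing true sites — mirroring the structure, not the identity,
  of a seven-site experimental outcome — one of which has single-sample
  support and is recovered only through the allowlist, plus eight decoys
  each violating exactly one rule (low reads ×2, single sample ×2,
  control-positive ×2, >4 mismatches ×2). Exact recovery (precision =
  recall = 1) is the acceptance property.

## Numerical conventions and tie-breaks

* Coordinates: 1-based inclusive c.-positions at all public interfaces
  (HGVS convention); 0-based half-open internally and in BED-like I/O.
* Delins decomposition: unit-cost edit-distance DP; among co-optimal
  scripts the traceback prefers substitutions/matches over gaps, which
  places gaps 5′-most (so `GCCCG→CCCC` reads as deletion at the first
  position plus substitution at the last, not the 3′-most alternative).
* Translation: standard nuclear code only; translation stops at the first
  stop codon; a stop is premature iff it is not the terminal codon, and a
  boundary-spanning stop is attributed to the exon holding its first base.
* Restriction matching is forward-strand with IUPAC expansion; the shipped
  BanII (`GRGCYC`) and AvaII (`GGWCC`) sites are palindromic, so this
  equals double-stranded search for them. Fragment lengths always sum to
  the input length; zero sites yield one fragment.
* Degenerate inputs: empty retained read set yields a zero-total table
  with an undefined-percent flag; empty record sets yield empty cluster
  and site lists; a spacer absent from its amplicon is an error, not a
  guess.

## Problem sizes

Checks run at: 10,000 reads × 240 bp amplicon for spectrum recovery
(exact at zero error; within ±1.5 percentage points of the realized
multinomial truth at 0.005); 15 planted sites across 4 × 20 kb toy
chromosomes with 12 samples (~23,000 records) for off-target recovery;
200-instance oracle-equivalence suites (interval clustering vs pairwise
connected components at ≤50 intervals, mismatch scanning vs sliding-window
Hamming, decomposition edit counts vs exhaustive DP at ≤8 nt); and ≥200
random coding fixtures for the frame-restoration property.

## Known limitations

* The dysferlin model is synthetic outside the constraint-pinned window;
  residue identities away from codons 1620–1631, exon boundaries other
  than the 44/45 region's relative placement, and all flanking sequence
  are fabrications consistent with, but not copies of, the real gene.
* Deletion outcomes (e.g. the −4 class) are quantified but not predicted;
  no microhomology model is included.
* The aligner prefers a single contiguous indel near the cut by
  construction of the scoring; complex multi-indel reads may normalise
  differently than a production quantifier would report them.
* Off-target scoring is an ordinal surrogate; scores are comparable within
  a run, not calibrated probabilities of cleavage.
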