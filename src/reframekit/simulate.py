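"""Seeded generators for every input the pipeline consumes.

All generators draw from a ``numpy.random.Generator`` seeded through the
dataset spec, so the same seed reproduces byte-identical outputs: coding
fixtures with injected frameshift lesions, amplicon FASTQ with a programmed
allele spectrum, toy genomes with planted off-target sites, and GUIDE-seq
alignment-record tables with planted integration sites, decoys, and uniform
background.

Default simulation conditions mirror the editing experiment this package
models: an allele spectrum dominated by the templated +1A insertion (62%)
over a -4 deletion (20%), other indels (10%) and unedited reads (8%) —
i.e. >90% total editing with >60% templated insertions — at 10,000 reads
with a 0.005 per-base substitution-error rate; GUIDE-seq samples come in
three edited replicates per primer group (GSP+/GSP-) plus matched
no-sgRNA controls, with Poisson read support around each planted site.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .coding import CodingModel, DelinsVariant, apply_variant, translate
from .guideseq import AlignmentRecord
from .coding import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = sorted({a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS)


# ---------------------------------------------------------------------------
# dataset spec

@dataclass
class AmpliconSimSpec:
    reference_length: int = 240
    spacer_start: int = 100  # 0-based protospacer start on the plus strand
    spacer_strand: str = "+"
    allele_spectrum: tuple[tuple[str, float], ...] = (
        ("+1A", 0.62), ("-4", 0.20), ("-2", 0.10), ("WT", 0.08),
    )
    n_reads: int = 10_000
    error_rate: float = 0.005
    quality_mean: float = 37.0
    quality_sd: float = 2.0
    reference: str | None = None  # explicit amplicon overrides the random one

    def validate(self):
        total = sum(f for _, f in self.allele_spectrum)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele spectrum sums to {total}, not 1")
        if self.n_reads < 0 or self.error_rate < 0:
            raise ValueError("counts and rates must be >= 0")


@dataclass
class PlantedSite:
    """One planted GUIDE-seq integration site."""

    name: str
    mismatch_count: int = 2
    mean_reads: float = 300.0
    n_edited_samples: int | None = None  # None = all edited samples
    in_controls: bool = False


@dataclass
class GuideseqSimSpec:
    n_chroms: int = 4
    chrom_length: int = 20_000
    samples_per_group: int = 3
    planted: tuple[PlantedSite, ...] = ()
    background_records_per_sample: int = 20
    read_length: int = 150
    jitter_sd: float = 3.0


@dataclass
class CdsFixtureSpec:
    n_codons: int = 60
    n_exons: int = 3
    lesion_net: int = -1  # net length change of the injected delins
    lesion_ref_len: int = 5


@dataclass
class SyntheticDatasetSpec:
    seed: int = 0
    amplicon: AmpliconSimSpec = field(default_factory=AmpliconSimSpec)
    guideseq: GuideseqSimSpec = field(default_factory=GuideseqSimSpec)
    cds: CdsFixtureSpec = field(default_factory=CdsFixtureSpec)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        h = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:4], "big"))


def spec_from_dict(d: dict) -> SyntheticDatasetSpec:
    amp = d.get("amplicon", {})
    if "allele_spectrum" in amp:
        amp["allele_spectrum"] = tuple(tuple(x) for x in amp["allele_spectrum"])
    gs = d.get("guideseq", {})
    if "planted" in gs:
        gs["planted"] = tuple(PlantedSite(**p) for p in gs["planted"])
    return SyntheticDatasetSpec(
        seed=int(d.get("seed", 0)),
        amplicon=AmpliconSimSpec(**amp),
        guideseq=GuideseqSimSpec(**gs),
        cds=CdsFixtureSpec(**d.get("cds", {})),
    )


def load_spec(path) -> SyntheticDatasetSpec:
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# coding-sequence fixtures

def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free random codons + TGA."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    body = [_SENSE[i] for i in rng.integers(0, len(_SENSE), n_codons - 2)]
    return "ATG" + "".join(body) + "TGA"


def make_cds_fixture(spec: SyntheticDatasetSpec) -> tuple[CodingModel, DelinsVariant]:
    """A random ORF with an injected delins of the requested net length.

    The lesion is placed in the middle exon; for frameshifting lesions the
    construction is re-drawn until the mutant allele carries a premature
    stop downstream of the lesion (verified by translation).
    """
    c = spec.cds
    if c.lesion_ref_len + max(0, -c.lesion_net) >= c.n_codons * 3 - 6:
        raise ValueError("lesion longer than the coding sequence")
    rng = spec.rng("cds")
    alt_len = c.lesion_ref_len + c.lesion_net
    if alt_len < 0:
        raise ValueError("lesion would have negative alt length")
    length = c.n_codons * 3
    for _ in range(1000):
        seq = random_orf(rng, c.n_codons)
        # exon tiling
        bounds = sorted(rng.choice(np.arange(2, length - 1), size=c.n_exons - 1,
                                   replace=False))
        exons, pos = [], 1
        for i, b in enumerate(list(bounds) + [length]):
            exons.append((str(i + 1), pos, int(b)))
            pos = int(b) + 1
        model = CodingModel("cds_fixture", seq, tuple(exons))
        start = int(rng.integers(length // 3, 2 * length // 3))
        ref = seq[start - 1 : start - 1 + c.lesion_ref_len]
        alt = "".join("ACGT"[i] for i in rng.integers(0, 4, alt_len)) if alt_len else ""
        if alt == ref:
            continue
        if alt_len == 0:
            # pure deletion: anchor so alt stays non-empty
            if start < 2:
                continue
            variant = DelinsVariant(start - 1, start - 1 + c.lesion_ref_len,
                                    seq[start - 2] + ref, seq[start - 2])
        else:
            variant = DelinsVariant(start, start + c.lesion_ref_len - 1, ref, alt)
        mutant = apply_variant(model, variant)
        if c.lesion_net % 3 != 0:
            _, stop = translate(mutant)
            # demand a premature stop strictly downstream of the lesion
            if stop is None or (stop - 1) * 3 < variant.start_c:
                continue
        return model, variant
    raise RuntimeError("could not construct a CDS fixture satisfying constraints")


# ---------------------------------------------------------------------------
# amplicon read simulation

def _apply_descriptor(ref: str, cut: int, expected_base: str, descriptor: str) -> str:
    """Realize an allele from an edit descriptor.

    Descriptors: ``WT``; ``+1A`` (or any ``+<len><bases>``) inserted at the
    cut; ``-<len>`` deleted around the cut; either may carry ``@<offset>``
    relative to the cut (e.g. ``+1A@5``, ``-4@-2``).
    """
    if descriptor == "WT":
        return ref
    body, _, off = descriptor.partition("@")
    offset = int(off) if off else 0
    pos = cut + offset
    if body.startswith("+"):
        i = 1
        while i < len(body) and body[i].isdigit():
            i += 1
        length = int(body[1:i])
        bases = body[i:] or expected_base * length
        if len(bases) != length:
            raise ValueError(f"descriptor {descriptor!r}: base count != length")
        return ref[:pos] + bases + ref[pos:]
    if body.startswith("-"):
        length = int(body[1:])
        start = pos - (length // 2) if not off else pos
        start = max(0, start)
        return ref[:start] + ref[start + length :]
    raise ValueError(f"unsupported edit descriptor {descriptor!r}")


def simulate_amplicon_reads(
    spec: SyntheticDatasetSpec,
) -> tuple[str, str, list, dict[str, int]]:
    """Draw reads multinomially from the programmed allele spectrum.

    Returns ``(reference, spacer, reads, truth)`` where ``truth`` maps each
    spectrum descriptor to its *realized* read count.  Reads cover the full
    amplicon (single-end), carry substitution errors at the programmed rate
    and Gaussian phred33 qualities clipped to [2, 41].
    """
    a = spec.amplicon
    a.validate()
    rng = spec.rng("amplicon")
    if a.reference is not None:
        ref = a.reference.upper()
    else:
        # random amplicon with an embedded NGG so the spacer is NGG-adjacent;
        # the base templating the +1 insertion is forced to match the first
        # "+1X" descriptor in the spectrum (the staggered-cut duplication)
        arr = rng.integers(0, 4, a.reference_length)
        ref = "".join("ACGT"[i] for i in arr)
        s = a.spacer_start
        ref = ref[: s + 20] + "A" + "GG" + ref[s + 23 :]
        plus1 = next(
            (d for d, _ in a.allele_spectrum
             if d.startswith("+1") and len(d) == 3), None
        )
        if plus1 is not None:
            dup_idx = s + 16 if a.spacer_strand == "+" else s + 3
            ref = ref[:dup_idx] + plus1[2] + ref[dup_idx + 1 :]
    s = a.spacer_start
    if a.spacer_strand == "+":
        spacer = ref[s : s + 20]
        cut = s + 17
        expected = ref[cut - 1]
    else:
        spacer = revcomp(ref[s : s + 20])
        cut = s + 3
        expected = ref[cut]
    alleles = {
        desc: _apply_descriptor(ref, cut, expected, desc)
        for desc, _ in a.allele_spectrum
    }
    probs = np.array([f for _, f in a.allele_spectrum])
    counts = rng.multinomial(a.n_reads, probs)
    truth = {desc: int(n) for (desc, _), n in zip(a.allele_spectrum, counts)}
    from .amplicon import SequencedRead

    reads: list[SequencedRead] = []
    idx = 0
    for (desc, _), n in zip(a.allele_spectrum, counts):
        allele = alleles[desc]
        arr0 = np.frombuffer(allele.encode(), dtype=np.uint8)
        for _ in range(n):
            arr = arr0.copy()
            if a.error_rate > 0:
                err = rng.random(len(arr)) < a.error_rate
                if err.any():
                    shifts = rng.integers(1, 4, int(err.sum()))
                    cur = np.searchsorted(_BASES, arr[err])
                    arr[err] = _BASES[(cur + shifts) % 4]
            quals = np.clip(
                np.rint(rng.normal(a.quality_mean, a.quality_sd, len(arr))), 2, 41
            ).astype(int)
            reads.append(
                SequencedRead(
                    read_id=f"sim_{idx}_{desc}",
                    bases=arr.tobytes().decode(),
                    quals="".join(chr(q + 33) for q in quals),
                )
            )
            idx += 1
    return ref, spacer, reads, truth


def write_fastq(reads, path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quals}\n")


# ---------------------------------------------------------------------------
# toy genomes with planted off-target sites

def guideseq_validation_plan() -> tuple[PlantedSite, ...]:
    """The standard off-target validation scenario: seven filter-passing
    true sites (one of them, mirroring the single-sample chromosome-5
    cluster, supported by a single sample and rescued only via the
    allowlist) plus eight decoys each violating exactly one rule:
    read support below the cluster cutoff, single-sample support,
    control contamination, or more mismatches than the prediction scan
    allows (hence never intersecting a predicted site).
    """
    true_sites = [
        PlantedSite(f"true{i}", mismatch_count=(i % 4) + 1, mean_reads=300.0)
        for i in range(1, 7)
    ]
    true_sites.append(
        PlantedSite("true7_allowlisted", mismatch_count=2, mean_reads=300.0,
                    n_edited_samples=1)
    )
    decoys = [
        PlantedSite("decoy_low_reads_1", 2, 80.0),
        PlantedSite("decoy_low_reads_2", 3, 60.0),
        PlantedSite("decoy_single_sample_1", 2, 300.0, n_edited_samples=1),
        PlantedSite("decoy_single_sample_2", 1, 300.0, n_edited_samples=1),
        PlantedSite("decoy_in_controls_1", 2, 300.0, in_controls=True),
        PlantedSite("decoy_in_controls_2", 3, 300.0, in_controls=True),
        PlantedSite("decoy_unpredicted_1", 6, 300.0),
        PlantedSite("decoy_unpredicted_2", 7, 300.0),
    ]
    return tuple(true_sites + decoys)


def planted_site_layout(spec: SyntheticDatasetSpec) -> dict[str, tuple[str, int, int]]:
    """Deterministic genome placement for the spec's planted sites.

    Maps each planted site name to ``(chrom, position, mismatch_count)``
    where ``position`` is the protospacer start; the cut (integration
    position) is ``position + 17``.  Used by both the toy-genome builder
    and the GUIDE-seq record simulator so they agree by construction.
    """
    g = spec.guideseq
    layout = {}
    for i, site in enumerate(g.planted):
        chrom = f"chr{(i % g.n_chroms) + 1}"
        position = 2_000 + (i // g.n_chroms) * 5_000
        layout[site.name] = (chrom, position, site.mismatch_count)
    return layout


def _mutate_spacer(rng, spacer: str, n_mismatches: int) -> str:
    pos = rng.choice(20, size=n_mismatches, replace=False)
    arr = list(spacer)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def make_toy_genome(
    spec: SyntheticDatasetSpec,
    spacer: str,
    plants: list[tuple[str, int, int]] | None = None,
    scan_threshold: int = 4,
) -> tuple[dict[str, str], list[tuple[str, int, int, int]]]:
    """Random chromosomes with NGG-adjacent sites planted at given
    mismatch counts.

    ``plants`` is a list of ``(chrom, position, mismatch_count)``; when
    None, sites derive from the GUIDE-seq planted-site table (one site per
    planted entry, spread across chromosomes).  A rejection step redraws
    any chromosome that accidentally contains an extra site within the
    scan threshold.  Returns the genome and a truth table of
    ``(chrom, position, strand_is_plus, mismatch_count)`` (plus strand
    only, as planted).
    """
    from .guideseq import predict_ots

    g = spec.guideseq
    rng = spec.rng("genome")
    spacer = spacer.upper()
    if plants is None:
        plants = [
            (chrom, position, mm)
            for chrom, position, mm in planted_site_layout(spec).values()
        ]
    if any(mm > len(spacer) for _, _, mm in plants):
        raise ValueError("planted mismatch count exceeds spacer length")
    for chrom, position, _ in plants:
        if position + 23 > g.chrom_length:
            raise ValueError("genome too small for requested plants")
    chrom_names = sorted({c for c, _, _ in plants} | {
        f"chr{i+1}" for i in range(g.n_chroms)
    })
    genome: dict[str, str] = {}
    truth: list[tuple[str, int, int, int]] = []
    for chrom in chrom_names:
        mine = [(pos, mm) for c, pos, mm in plants if c == chrom]
        for _ in range(50):
            arr = rng.integers(0, 4, g.chrom_length)
            seq = "".join("ACGT"[i] for i in arr)
            for pos, mm in mine:
                site = _mutate_spacer(rng, spacer, mm) + "T" + "GG"
                seq = seq[:pos] + site + seq[pos + 23 :]
            found = predict_ots({chrom: seq}, spacer, max_mismatches=scan_threshold)
            expected = {(pos, mm) for pos, mm in mine if mm <= scan_threshold}
            got = {(h.position, h.mismatch_count) for h in found}
            if got == expected:
                genome[chrom] = seq
                break
        else:
            raise RuntimeError(f"could not build clean chromosome {chrom}")
        truth.extend((chrom, pos, 1, mm) for pos, mm in mine)
    return genome, truth


# ---------------------------------------------------------------------------
# GUIDE-seq record simulation

def simulate_guideseq(
    spec: SyntheticDatasetSpec,
    site_positions: dict[str, tuple[str, int]] | None = None,
) -> list[AlignmentRecord]:
    """Per-sample tag-integration alignment records.

    For each planted site and participating edited sample, read counts are
    drawn Poisson around the site's mean and read intervals jittered around
    the integration position (half on each strand, so the modal 5' end
    estimator sees both orientations).  Sites with ``in_controls`` also
    emit records in control samples; uniform background singleton records
    are added per sample.
    """
    g = spec.guideseq
    rng = spec.rng("guideseq")
    if site_positions is None:
        site_positions = {
            name: (chrom, position + 17)  # tag integration at the cut
            for name, (chrom, position, _) in planted_site_layout(spec).items()
        }
    samples = []
    for group in ("GSP_plus", "GSP_minus", "ctrl_plus", "ctrl_minus"):
        for i in range(g.samples_per_group):
            samples.append((f"{group}_s{i+1}", group))
    records: list[AlignmentRecord] = []
    for site in g.planted:
        chrom, position = site_positions[site.name]
        for group in ("GSP_plus", "GSP_minus"):
            pool = [s for s in samples if s[1] == group]
            n_use = site.n_edited_samples
            use = pool if n_use is None else pool[:n_use]
            for sample_id, grp in use:
                records.extend(
                    _site_records(rng, g, sample_id, grp, chrom, position, site.mean_reads)
                )
        if site.in_controls:
            for sample_id, grp in samples:
                if grp in ("ctrl_plus", "ctrl_minus"):
                    records.extend(
                        _site_records(rng, g, sample_id, grp, chrom, position,
                                      site.mean_reads / 2)
                    )
    # uniform background: isolated singleton records
    chroms = sorted({c for c, _ in site_positions.values()} | {
        f"chr{i+1}" for i in range(g.n_chroms)
    })
    for sample_id, grp in samples:
        for _ in range(g.background_records_per_sample):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, g.chrom_length - g.read_length))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                AlignmentRecord(sample_id, grp, chrom, start,
                                start + g.read_length, strand)
            )
    return records


def _site_records(rng, g: GuideseqSimSpec, sample_id, group, chrom, position,
                  mean_reads) -> list[AlignmentRecord]:
    n = int(rng.poisson(mean_reads))
    out = []
    for _ in range(max(n, 1)):
        jitter = int(np.rint(rng.normal(0, g.jitter_sd)))
        if rng.random() < 0.5:
            start = position  # + strand read anchored at the integration site
            out.append(AlignmentRecord(sample_id, group, chrom,
                                       max(0, start + min(jitter, 0)),
                                       start + g.read_length, "+"))
        else:
            end = position + max(jitter, 0)
            out.append(AlignmentRecord(sample_id, group, chrom,
                                       max(0, end - g.read_length), end, "-"))
    return out


def write_manifest(path, spec: SyntheticDatasetSpec, outputs: dict[str, str]) -> None:
    payload = {
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
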