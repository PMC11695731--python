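"""GUIDE-seq downstream analysis: clustering, filtering, and prediction.

The pipeline ingests aligned tag-integration records (BED-like TSV), never
raw reads.  Per sample, overlapping alignments are clustered into connected
components; each cluster's tag-integration position is the modal
strand-aware 5' read end.  Clusters are intersected across samples, then
filtered by the read-support rules: a per-sample cluster read cutoff
(default 200), positivity in at least two edited samples within the GSP+
or the GSP- primer group, and negativity in all control samples; an
explicit allowlist can rescue sites (e.g. a known single-sample site).
Retained sites are intersected with mismatch-enumerated off-target
predictions, and reads are summed per primer group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import revcomp

EDITED_GROUPS = ("GSP_plus", "GSP_minus")
CONTROL_GROUPS = ("ctrl_plus", "ctrl_minus")


@dataclass(frozen=True)
class AlignmentRecord:
    sample_id: str
    group: str  # GSP_plus | GSP_minus | ctrl_plus | ctrl_minus
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty interval")
        if self.group not in EDITED_GROUPS + CONTROL_GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class SampleCluster:
    chrom: str
    start: int
    end: int
    read_count: int
    integration_position: int
    sample_id: str
    group: str


@dataclass
class PredictedOTS:
    chrom: str
    position: int  # 0-based start of the protospacer on the plus strand
    strand: str
    site_sequence: str  # protospacer+PAM as it reads in guide orientation
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # 1-based guide positions (20 = PAM-proximal)
    score: float
    annotation: str | None = None  # exonic | intronic | intergenic
    is_on_target: bool = False


@dataclass
class CandidateSite:
    chrom: str
    start: int
    end: int
    integration_position: int
    per_sample_read_counts: dict[str, int] = field(default_factory=dict)
    sample_groups: dict[str, str] = field(default_factory=dict)
    allowlisted: bool = False
    predicted_match: PredictedOTS | None = None

    @property
    def n_positive_edited_samples(self) -> int:
        return sum(1 for g in self.sample_groups.values() if g in EDITED_GROUPS)

    def n_positive_in_group(self, group: str) -> int:
        return sum(1 for g in self.sample_groups.values() if g == group)

    @property
    def control_positive(self) -> bool:
        return any(g in CONTROL_GROUPS for g in self.sample_groups.values())

    def control_positive_at(self, min_reads: int) -> bool:
        """Control positivity with a minimum control-cluster read count
        (a lone background read does not constitute a detection)."""
        return any(
            self.sample_groups[s] in CONTROL_GROUPS and n >= min_reads
            for s, n in self.per_sample_read_counts.items()
        )

    def group_reads(self, group: str) -> int:
        return sum(
            n for s, n in self.per_sample_read_counts.items()
            if self.sample_groups[s] == group
        )

    @property
    def gsp_plus_reads(self) -> int:
        return self.group_reads("GSP_plus")

    @property
    def gsp_minus_reads(self) -> int:
        return self.group_reads("GSP_minus")

    @property
    def max_cluster_reads(self) -> int:
        edited = [n for s, n in self.per_sample_read_counts.items()
                  if self.sample_groups[s] in EDITED_GROUPS]
        return max(edited, default=0)


@dataclass
class FilterParams:
    min_reads_per_cluster: int = 200
    min_positive_edited_samples: int = 2
    require_control_negative: bool = True
    # minimum control-cluster reads for a site to count as control-positive
    control_positivity_min_reads: int = 2
    cross_sample_match_tolerance_bp: int = 10
    allowlist: list[tuple[str, int, int]] = field(default_factory=list)
    # 'per_sample' applies the read cutoff to the best member cluster;
    # 'group_sum' applies it to reads summed within a primer group.
    read_cutoff_mode: str = "per_sample"

    def __post_init__(self):
        if self.min_reads_per_cluster < 0 or self.min_positive_edited_samples < 0:
            raise ValueError("thresholds must be >= 0")
        if self.read_cutoff_mode not in ("per_sample", "group_sum"):
            raise ValueError("read_cutoff_mode must be per_sample or group_sum")


# ---------------------------------------------------------------------------
# clustering

def cluster_alignments(records: list[AlignmentRecord]) -> list[SampleCluster]:
    """Connected components under >=1 bp interval overlap, per chromosome.

    All records must share one sample_id.  Cluster interval is the union of
    member intervals; read_count is the member count.
    """
    if not records:
        return []
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise ValueError("cluster_alignments expects records from one sample")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValueError("inconsistent group labels within one sample")
    clusters: list[SampleCluster] = []
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        members: list[AlignmentRecord] = []
        cur_end = None
        for r in recs:
            if cur_end is None or r.start < cur_end:  # half-open: touch != overlap
                members.append(r)
                cur_end = max(cur_end or r.end, r.end)
            else:
                clusters.append(_finalize_cluster(members))
                members = [r]
                cur_end = r.end
        if members:
            clusters.append(_finalize_cluster(members))
    return clusters


def call_integration_position(members: list[AlignmentRecord]) -> int:
    """Modal strand-aware 5' end of member reads; ties -> smaller coord."""
    if not members:
        raise ValueError("empty cluster")
    counts = Counter(r.five_prime for r in members)
    best = max(counts.values())
    return min(p for p, n in counts.items() if n == best)


def _finalize_cluster(members: list[AlignmentRecord]) -> SampleCluster:
    return SampleCluster(
        chrom=members[0].chrom,
        start=min(r.start for r in members),
        end=max(r.end for r in members),
        read_count=len(members),
        integration_position=call_integration_position(members),
        sample_id=members[0].sample_id,
        group=members[0].group,
    )


# ---------------------------------------------------------------------------
# cross-sample intersection and filtering

def intersect_samples(
    clusters: list[SampleCluster], params: FilterParams | None = None
) -> list[CandidateSite]:
    """Merge per-sample clusters into candidate sites.

    Clusters on the same chromosome whose integration positions lie within
    ``cross_sample_match_tolerance_bp`` are chained into one site
    (single-linkage on the sorted positions).
    """
    params = params or FilterParams()
    tol = params.cross_sample_match_tolerance_bp
    sites: list[CandidateSite] = []
    by_chrom: dict[str, list[SampleCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: (c.integration_position, c.sample_id))
        block: list[SampleCluster] = []
        for c in cs:
            if block and c.integration_position - block[-1].integration_position > tol:
                sites.append(_finalize_site(block))
                block = []
            block.append(c)
        if block:
            sites.append(_finalize_site(block))
    return sites


def _finalize_site(block: list[SampleCluster]) -> CandidateSite:
    site = CandidateSite(
        chrom=block[0].chrom,
        start=min(c.start for c in block),
        end=max(c.end for c in block),
        integration_position=call_integration_position_from_clusters(block),
    )
    for c in block:
        site.per_sample_read_counts[c.sample_id] = (
            site.per_sample_read_counts.get(c.sample_id, 0) + c.read_count
        )
        site.sample_groups[c.sample_id] = c.group
    return site


def call_integration_position_from_clusters(block: list[SampleCluster]) -> int:
    counts = Counter()
    for c in block:
        counts[c.integration_position] += c.read_count
    best = max(counts.values())
    return min(p for p, n in counts.items() if n == best)


def _overlaps_allowlist(site: CandidateSite, allowlist) -> bool:
    return any(
        site.chrom == chrom and site.start < end and site.end > start
        for chrom, start, end in allowlist
    )


def filter_sites(
    sites: list[CandidateSite], params: FilterParams | None = None
) -> list[CandidateSite]:
    """Apply the read-count / replication / control-negativity rules.

    The per-cluster read cutoff is applied first, so *positivity* counts
    only samples whose member cluster carries at least
    ``min_reads_per_cluster`` reads (a stray background read does not make
    a sample positive).  A site is retained iff at least
    ``min_positive_edited_samples`` samples are positive within the GSP+
    group or within the GSP- group AND (when required) no control sample
    shows any cluster at the site — or it overlaps the allowlist, which
    waives the replication requirement (but not the read cutoff or control
    negativity — a documented single-sample cluster still needs real read
    support).  In ``group_sum`` mode the read cutoff applies to reads
    summed within a primer group instead, with presence-based positivity.
    """
    params = params or FilterParams()
    out: list[CandidateSite] = []
    for site in sites:
        allowlisted = params.allowlist and any(
            site.chrom == chrom and start <= site.integration_position < end
            for chrom, start, end in params.allowlist
        )
        if params.read_cutoff_mode == "per_sample":
            def n_strong(group):
                return sum(
                    1 for s, n in site.per_sample_read_counts.items()
                    if site.sample_groups[s] == group
                    and n >= params.min_reads_per_cluster
                )

            min_samples = 1 if allowlisted else params.min_positive_edited_samples
            replicated = (
                n_strong("GSP_plus") >= min_samples
                or n_strong("GSP_minus") >= min_samples
            )
        else:
            reads_ok = max(site.gsp_plus_reads, site.gsp_minus_reads) >= (
                params.min_reads_per_cluster
            )
            min_samples = 1 if allowlisted else params.min_positive_edited_samples
            replicated = reads_ok and (
                site.n_positive_in_group("GSP_plus") >= min_samples
                or site.n_positive_in_group("GSP_minus") >= min_samples
            )
        control_ok = not (
            params.require_control_negative
            and site.control_positive_at(params.control_positivity_min_reads)
        )
        if replicated and control_ok:
            site.allowlisted = bool(allowlisted)
            out.append(site)
    return out


# ---------------------------------------------------------------------------
# off-target prediction

def _pam_distal_weights(length: int = 20) -> np.ndarray:
    # weight for a mismatch at guide position i (1-based; 20 = PAM-proximal):
    # PAM-proximal mismatches are penalized more (smaller weight)
    return (length + 1 - np.arange(1, length + 1)) / (length + 1)

_WEIGHTS = _pam_distal_weights()


def _score(mismatch_positions: tuple[int, ...]) -> float:
    score = 1.0
    for p in mismatch_positions:
        score *= _WEIGHTS[p - 1]
    return score


def predict_ots(
    genome: dict[str, str],
    spacer: str,
    max_mismatches: int = 4,
    include_nag: bool = False,
) -> list[PredictedOTS]:
    """Enumerate NGG-adjacent 20-mers within a mismatch budget of the spacer.

    Both strands are scanned; each hit carries its mismatch positions
    (1-based guide coordinates, 20 = PAM-proximal) and a positional-weight
    score in (0, 1] that decreases more sharply for PAM-proximal
    mismatches.  The 0-mismatch hit is flagged as the on-target site.
    """
    spacer = spacer.upper()
    if len(spacer) != 20:
        raise ValueError("spacer must be 20 nt")
    pam2 = ("GG", "AG") if include_nag else ("GG",)
    hits: list[PredictedOTS] = []
    spacer_arr = np.frombuffer(spacer.encode(), dtype=np.uint8)
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            n = len(s) - 23 + 1
            if n <= 0:
                continue
            for i in range(n):
                if s[i + 21 : i + 23] not in pam2:
                    continue
                mm = np.nonzero(arr[i : i + 20] != spacer_arr)[0]
                if len(mm) > max_mismatches:
                    continue
                positions = tuple(int(p) + 1 for p in mm)
                pos = i if strand == "+" else len(s) - (i + 23)
                hits.append(
                    PredictedOTS(
                        chrom=chrom,
                        position=pos,
                        strand=strand,
                        site_sequence=s[i : i + 23],
                        mismatch_count=len(mm),
                        mismatch_positions=positions,
                        score=_score(positions),
                        is_on_target=len(mm) == 0,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.position, h.strand))
    return hits


def annotate_predictions(
    predictions: list[PredictedOTS],
    exon_intervals: list[tuple[str, int, int]] | None,
    intron_intervals: list[tuple[str, int, int]] | None = None,
) -> list[PredictedOTS]:
    """Label predictions exonic / intronic / intergenic by interval overlap."""
    for p in predictions:
        p.annotation = "intergenic"
        span = (p.position, p.position + 23)
        if intron_intervals and _hit(p.chrom, span, intron_intervals):
            p.annotation = "intronic"
        if exon_intervals and _hit(p.chrom, span, exon_intervals):
            p.annotation = "exonic"
    return predictions


def _hit(chrom, span, intervals) -> bool:
    return any(c == chrom and span[0] < e and span[1] > s for c, s, e in intervals)


def select_for_validation(
    predictions: list[PredictedOTS],
    k: int = 10,
    exclude_on_target: bool = True,
) -> list[PredictedOTS]:
    """Top-k by score (ties by mismatch count then coordinate) union all
    exonic predictions, duplicates collapsed, order preserved by rank."""
    pool = [p for p in predictions if not (exclude_on_target and p.is_on_target)]
    ranked = sorted(pool, key=lambda p: (-p.score, p.mismatch_count, p.chrom, p.position))
    chosen = ranked[:k]
    seen = {id(p) for p in chosen}
    for p in ranked[k:]:
        if p.annotation == "exonic" and id(p) not in seen:
            chosen.append(p)
            seen.add(id(p))
    return chosen


def annotate_with_predictions(
    sites: list[CandidateSite],
    predictions: list[PredictedOTS],
    tolerance_bp: int = 25,
) -> list[CandidateSite]:
    """Match each site to the nearest prediction within tolerance.

    Distance is measured from the site's integration position to the
    prediction's cut position (protospacer position 17|18 boundary);
    equidistant predictions resolve to the smaller coordinate.  Unmatched
    sites keep ``predicted_match=None``.
    """
    for site in sites:
        best = None
        best_key = None
        for p in predictions:
            if p.chrom != site.chrom:
                continue
            cut = p.position + 17 if p.strand == "+" else p.position + 6
            dist = abs(cut - site.integration_position)
            if dist > tolerance_bp:
                continue
            key = (dist, p.position)
            if best_key is None or key < best_key:
                best, best_key = p, key
        site.predicted_match = best
    return sites


# ---------------------------------------------------------------------------
# I/O

TSV_COLUMNS = ["chrom", "start", "end", "strand", "sample_id", "group"]


def read_alignment_tsv(path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    return [
        AlignmentRecord(
            sample_id=str(r.sample_id), group=r.group, chrom=str(r.chrom),
            start=int(r.start), end=int(r.end), strand=r.strand,
        )
        for r in df.itertuples()
    ]


def write_alignment_tsv(records: list[AlignmentRecord], path) -> None:
    pd.DataFrame(
        [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "strand": r.strand, "sample_id": r.sample_id, "group": r.group}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def site_report(sites: list[CandidateSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        m = s.predicted_match
        rows.append(
            {
                "chrom": s.chrom,
                "integration_position": s.integration_position,
                "start": s.start,
                "end": s.end,
                "n_positive_edited_samples": s.n_positive_edited_samples,
                "gsp_plus_reads": s.gsp_plus_reads,
                "gsp_minus_reads": s.gsp_minus_reads,
                "control_positive": s.control_positive,
                "allowlisted": s.allowlisted,
                "predicted_site": m.site_sequence if m else None,
                "mismatch_count": m.mismatch_count if m else None,
                "per_sample_counts": ";".join(
                    f"{k}:{v}" for k, v in sorted(s.per_sample_read_counts.items())
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    records: list[AlignmentRecord],
    predictions: list[PredictedOTS] | None = None,
    params: FilterParams | None = None,
    prediction_tolerance_bp: int = 25,
    require_predicted: bool = True,
) -> list[CandidateSite]:
    """The full downstream chain: cluster -> intersect -> filter -> annotate.

    When predictions are supplied and ``require_predicted`` is set, only
    filtered sites matching a predicted off-target (or allowlisted sites)
    are reported — the GUIDE-seq/prediction intersection step.
    """
    params = params or FilterParams()
    by_sample: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    clusters: list[SampleCluster] = []
    for sample in sorted(by_sample):
        clusters.extend(cluster_alignments(by_sample[sample]))
    sites = intersect_samples(clusters, params)
    sites = filter_sites(sites, params)
    if predictions is not None:
        sites = annotate_with_predictions(sites, predictions, prediction_tolerance_bp)
        if require_predicted:
            sites = [s for s in sites if s.predicted_match or s.allowlisted]
    return sites
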