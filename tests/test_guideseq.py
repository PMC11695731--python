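"""guideseq_offtarget: clustering, intersection, filters, prediction."""

import pytest

import oracles
from reframekit.guideseq import (
    AlignmentRecord,
    FilterParams,
    PredictedOTS,
    annotate_predictions,
    annotate_with_predictions,
    call_integration_position,
    cluster_alignments,
    filter_sites,
    intersect_samples,
    predict_ots,
    run_pipeline,
    select_for_validation,
)
from reframekit.simulate import (
    PlantedSite,
    SyntheticDatasetSpec,
    make_toy_genome,
    planted_site_layout,
    simulate_guideseq,
)


def rec(start, end, sample="s1", group="GSP_plus", chrom="chr1", strand="+"):
    return AlignmentRecord(sample, group, chrom, start, end, strand)


class TestClustering:
    def test_disjoint_reads_two_clusters(self):
        clusters = cluster_alignments([rec(0, 10), rec(50, 60)])
        assert [c.read_count for c in clusters] == [1, 1]

    def test_transitive_chain_one_cluster(self):
        clusters = cluster_alignments([rec(0, 10), rec(8, 20), rec(18, 30)])
        assert len(clusters) == 1 and clusters[0].read_count == 3
        assert (clusters[0].start, clusters[0].end) == (0, 30)

    def test_touching_halfopen_do_not_overlap(self):
        clusters = cluster_alignments([rec(0, 10), rec(10, 20)])
        assert len(clusters) == 2

    def test_empty(self):
        assert cluster_alignments([]) == []

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_alignments([rec(0, 10, "s1"), rec(0, 10, "s2")])

    def test_matches_connected_components_oracle(self, rng):
        """200 random instances of <=50 intervals."""
        for _ in range(200):
            n = int(rng.integers(1, 51))
            intervals = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                intervals.append((s, s + int(rng.integers(1, 40))))
            records = [rec(s, e) for s, e in intervals]
            clusters = cluster_alignments(records)
            comps = oracles.overlap_components(intervals)
            got = sorted(
                (c.start, c.end, c.read_count) for c in clusters
            )
            expected = sorted(
                (
                    min(intervals[i][0] for i in comp),
                    max(intervals[i][1] for i in comp),
                    len(comp),
                )
                for comp in comps
            )
            assert got == expected


class TestIntegrationPosition:
    def test_shared_five_prime(self):
        members = [rec(100, 200), rec(100, 190), rec(100, 260)]
        assert call_integration_position(members) == 100

    def test_mode(self):
        members = [rec(100, 200)] * 3 + [rec(105, 200)] * 2
        assert call_integration_position(members) == 100

    def test_tie_breaks_to_smaller(self):
        members = [rec(100, 200)] * 2 + [rec(105, 200)] * 2
        assert call_integration_position(members) == 100

    def test_minus_strand_uses_end(self):
        members = [rec(100, 250, strand="-")] * 2 + [rec(90, 250, strand="-")]
        assert call_integration_position(members) == 250


class TestIntersectAndFilter:
    def _clusters(self, spec_list):
        # spec_list: (sample, group, integration_pos, reads)
        from reframekit.guideseq import SampleCluster

        return [
            SampleCluster("chr1", pos - 50, pos + 50, reads, pos, sample, group)
            for sample, group, pos, reads in spec_list
        ]

    def test_three_samples_merge(self):
        sites = intersect_samples(self._clusters([
            ("e1", "GSP_plus", 1000, 300),
            ("e2", "GSP_plus", 1004, 280),
            ("e3", "GSP_minus", 998, 260),
        ]))
        assert len(sites) == 1
        assert sites[0].n_positive_edited_samples == 3
        assert not sites[0].control_positive

    def test_control_only_site_flagged(self):
        sites = intersect_samples(self._clusters([("c1", "ctrl_plus", 500, 300)]))
        assert sites[0].control_positive

    def test_distant_sites_never_merge(self):
        sites = intersect_samples(self._clusters([
            ("e1", "GSP_plus", 1000, 300),
            ("e2", "GSP_plus", 2000, 300),
        ]))
        assert len(sites) == 2

    def test_filter_semantics(self):
        params = FilterParams()
        retained = filter_sites(intersect_samples(self._clusters([
            ("e1", "GSP_plus", 1000, 250),
            ("e2", "GSP_plus", 1002, 230),
        ])), params)
        assert len(retained) == 1
        removed = filter_sites(intersect_samples(self._clusters([
            ("e1", "GSP_plus", 5000, 199),
            ("e2", "GSP_plus", 5002, 150),
        ])), params)
        assert removed == []
        single = filter_sites(intersect_samples(self._clusters([
            ("e1", "GSP_plus", 9000, 400),
        ])), params)
        assert single == []

    def test_control_negative_rule(self):
        clusters = self._clusters([
            ("e1", "GSP_plus", 1000, 250),
            ("e2", "GSP_plus", 1002, 230),
            ("c1", "ctrl_plus", 1001, 40),
        ])
        assert filter_sites(intersect_samples(clusters), FilterParams()) == []
        relaxed = FilterParams(require_control_negative=False)
        assert len(filter_sites(intersect_samples(clusters), relaxed)) == 1

    def test_allowlist_rescues_single_sample_site(self):
        clusters = self._clusters([("e1", "GSP_plus", 9000, 400)])
        params = FilterParams(allowlist=[("chr1", 8950, 9050)])
        retained = filter_sites(intersect_samples(clusters), params)
        assert len(retained) == 1 and retained[0].allowlisted

    def test_filters_monotone_in_thresholds(self, rng):
        clusters = self._clusters([
            (f"e{i}", "GSP_plus", int(p), int(r))
            for i, (p, r) in enumerate(
                zip(rng.integers(0, 50_000, 40), rng.integers(50, 500, 40))
            )
        ])
        sites = intersect_samples(clusters)
        prev = None
        for cutoff in (50, 150, 250, 400):
            n = len(filter_sites(sites, FilterParams(min_reads_per_cluster=cutoff,
                                                     min_positive_edited_samples=1)))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for min_samples in (1, 2, 3):
            n = len(filter_sites(sites, FilterParams(
                min_reads_per_cluster=0,
                min_positive_edited_samples=min_samples)))
            if prev is not None:
                assert n <= prev
            prev = n


SPACER = "GACGTTACCGGATCAAGCTT"


class TestPredictOts:
    def test_exact_site_found(self):
        genome = {"chr1": "T" * 50 + SPACER + "AGG" + "T" * 50}
        hits = predict_ots(genome, SPACER)
        assert len(hits) == 1
        assert hits[0].mismatch_count == 0 and hits[0].is_on_target

    def test_planted_three_mismatches(self):
        mutated = "TTT" + SPACER[3:]
        genome = {"chr1": "C" * 40 + mutated + "TGG" + "C" * 40}
        hits = predict_ots(genome, SPACER)
        mm = [h for h in hits if h.position == 40]
        assert mm and mm[0].mismatch_count == sum(
            a != b for a, b in zip(mutated, SPACER)
        )
        assert set(mm[0].mismatch_positions) == {
            i + 1 for i, (a, b) in enumerate(zip(mutated, SPACER)) if a != b
        }

    def test_five_mismatches_absent(self):
        mutated = "".join("A" if b != "A" else "C" for b in SPACER[:5]) + SPACER[5:]
        assert sum(a != b for a, b in zip(mutated, SPACER)) == 5
        genome = {"chr1": "C" * 40 + mutated + "TGG" + "C" * 40}
        assert predict_ots(genome, SPACER, max_mismatches=4) == []

    def test_matches_hamming_oracle(self, rng):
        spec = SyntheticDatasetSpec(seed=21)
        spec.guideseq = type(spec.guideseq)(n_chroms=2, chrom_length=3000)
        plants = [("chr1", 500, 0), ("chr1", 1500, 2), ("chr2", 800, 4)]
        genome, _ = make_toy_genome(spec, SPACER, plants=plants)
        got = {
            (h.chrom, h.position, h.strand, h.mismatch_count)
            for h in predict_ots(genome, SPACER, 4)
        }
        assert got == oracles.hamming_scan(genome, SPACER, 4)

    def test_pam_proximal_mismatches_score_lower(self):
        distal = PredictedOTS("c", 0, "+", "x", 1, (1,), 0.0)
        proximal = PredictedOTS("c", 0, "+", "x", 1, (20,), 0.0)
        from reframekit.guideseq import _score

        assert _score((1,)) > _score((20,))
        assert _score(()) == 1.0


class TestSelectForValidation:
    def _preds(self, n, exonic_ranks=()):
        preds = []
        for i in range(n):
            p = PredictedOTS("chr1", i * 100, "+", "x", i % 5, (1,) * (i % 5),
                             score=1.0 / (i + 1))
            p.annotation = "exonic" if i in exonic_ranks else "intergenic"
            preds.append(p)
        return preds

    def test_topk_union_exonic(self):
        preds = self._preds(12, exonic_ranks=(1, 10, 11))
        chosen = select_for_validation(preds, k=10)
        # top-10 (one exonic among them) union the 2 exonic outside: 10+3-1
        assert len(chosen) == 12
        assert all(p in chosen for p in preds if p.annotation == "exonic")

    def test_fewer_than_k(self):
        preds = self._preds(4)
        assert len(select_for_validation(preds, k=10)) == 4


class TestAnnotateWithPredictions:
    def test_nearest_within_tolerance(self):
        from reframekit.guideseq import CandidateSite

        site = CandidateSite("chr1", 950, 1050, integration_position=1000)
        near = PredictedOTS("chr1", 990, "+", "x", 2, (1, 2), 0.5)  # cut 1007
        far = PredictedOTS("chr1", 2000, "+", "x", 1, (3,), 0.9)
        annotate_with_predictions([site], [near, far], tolerance_bp=25)
        assert site.predicted_match is near

    def test_unmatched_flagged(self):
        from reframekit.guideseq import CandidateSite

        site = CandidateSite("chr1", 950, 1050, integration_position=1000)
        annotate_with_predictions([site], [], tolerance_bp=25)
        assert site.predicted_match is None

    def test_equidistant_tie_smaller_coordinate(self):
        from reframekit.guideseq import CandidateSite

        site = CandidateSite("chr1", 0, 2000, integration_position=1000)
        a = PredictedOTS("chr1", 983 - 10, "+", "x", 1, (1,), 0.5)  # cut 990
        b = PredictedOTS("chr1", 993, "+", "x", 1, (1,), 0.5)  # cut 1010
        annotate_with_predictions([site], [b, a], tolerance_bp=25)
        assert site.predicted_match is a


class TestPipelineRecovery:
    def build(self, seed=3):
        plants = [
            PlantedSite(f"true{i}", mismatch_count=(i % 4) + 1, mean_reads=300)
            for i in range(6)
        ]
        plants.append(PlantedSite("true7_allow", 2, 300.0, n_edited_samples=1))
        decoys = [
            PlantedSite("decoy_low1", 2, 80.0),
            PlantedSite("decoy_low2", 3, 60.0),
            PlantedSite("decoy_single1", 2, 300.0, n_edited_samples=1),
            PlantedSite("decoy_single2", 1, 300.0, n_edited_samples=1),
            PlantedSite("decoy_ctrl1", 2, 300.0, in_controls=True),
            PlantedSite("decoy_ctrl2", 3, 300.0, in_controls=True),
            PlantedSite("decoy_unpred1", 6, 300.0),
            PlantedSite("decoy_unpred2", 7, 300.0),
        ]
        spec = SyntheticDatasetSpec(seed=seed)
        spec.guideseq.planted = tuple(plants + decoys)
        genome, _ = make_toy_genome(spec, SPACER)
        layout = planted_site_layout(spec)
        records = simulate_guideseq(spec)
        preds = predict_ots(genome, SPACER, 4)
        truth = {
            (layout[p.name][0], layout[p.name][1] + 17) for p in plants
        }
        return spec, layout, records, preds, truth

    def test_exact_recovery_with_allowlist(self):
        spec, layout, records, preds, truth = self.build()
        chrom, pos, _ = layout["true7_allow"]
        params = FilterParams(allowlist=[(chrom, pos, pos + 23)])
        sites = run_pipeline(records, preds, params)
        got = {(s.chrom, s.integration_position) for s in sites}
        assert got == truth  # precision = recall = 1

    def test_allowlist_site_lost_without_allowlist(self):
        spec, layout, records, preds, truth = self.build()
        sites = run_pipeline(records, preds, FilterParams())
        got = {(s.chrom, s.integration_position) for s in sites}
        chrom, pos, _ = layout["true7_allow"]
        assert got == truth - {(chrom, pos + 17)}

    def test_read_conservation(self):
        spec, layout, records, preds, truth = self.build()
        sites = run_pipeline(records, preds, FilterParams())
        total_edited = sum(
            1 for r in records if r.group in ("GSP_plus", "GSP_minus")
        )
        claimed = sum(s.gsp_plus_reads + s.gsp_minus_reads for s in sites)
        assert claimed <= total_edited
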