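"""Window dosage likelihoods, chromosome segmentation, aneuploidy calls
and per-gene annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from allohe import (
    annotate_genes,
    detect_aneuploidy,
    segment_chromosome,
    structure_report,
    window_dosage,
)
from allohe.dosage import DosageSegment, SegmentationParams, segments_to_bed
from conftest import cultivar_track


def brute_force_dose(alt, depth, ploidy, eps):
    """Independent grid evaluation: per-dose product of binomial pmfs."""
    best, best_ll = None, -np.inf
    for d in range(ploidy + 1):
        p = (1 - eps) * d / ploidy + eps * (1 - d / ploidy)
        ll = float(np.sum(binom.logpmf(alt, depth, p)))
        if ll > best_ll:
            best, best_ll = d, ll
    return best


class TestWindowDosage:
    def test_two_thirds_frequency_calls_b2(self):
        depth = np.full(25, 90)
        alt = np.rint(depth * 0.66)
        dose, ll = window_dosage(alt, depth, ploidy=3)
        assert dose == 2
        assert ll.shape == (4,)

    def test_saturated_frequency_calls_b3(self):
        depth = np.full(25, 90)
        dose, _ = window_dosage(depth.copy(), depth, ploidy=3)
        assert dose == 3

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            depth = rng.integers(10, 60, size=20)
            alt = rng.binomial(depth, rng.uniform(0, 1))
            dose, ll = window_dosage(alt, depth, ploidy=3, eps=0.005)
            assert dose == brute_force_dose(alt, depth, 3, 0.005)
            # full vector agrees entry-wise with the independent evaluation
            for d in range(4):
                p = 0.995 * d / 3 + 0.005 * (1 - d / 3)
                assert ll[d] == pytest.approx(float(binom.logpmf(alt, depth, p).sum()))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_dosage(np.array([]), np.array([]), 3)


def _uniform_track(n, f, depth=90, chrom="chr01", sites_per_gene=5):
    pos = np.arange(1, n + 1) * 1000
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "gene_index": np.arange(n) // sites_per_gene,
            "f": f if np.ndim(f) else np.full(n, float(f)),
            "depth": depth,
        }
    )


class TestSegmentChromosome:
    def test_uniform_baseline_single_segment(self):
        track = _uniform_track(300, 2 / 3)
        segs = segment_chromosome(track, 3)
        assert len(segs) == 1
        assert segs[0].label == "B2:A1"
        assert segs[0].n_snps == 300

    def test_tiny_track_uncallable(self):
        track = _uniform_track(5, 2 / 3)
        segs = segment_chromosome(track, 3)
        assert len(segs) == 1
        assert segs[0].label == "uncallable"

    def test_interior_b3_segment_recovered(self, recombined_abb):
        # chr04 of allo1: B2 baseline, B1 genes 20-49, B3 genes 70-99
        track = cultivar_track(recombined_abb, "allo1")
        t4 = track[track["chrom"] == "chr04"]
        segs = segment_chromosome(
            t4, 3, gene_models=recombined_abb.gene_models
        )
        labels = [s.label for s in segs]
        assert labels == ["B2:A1", "B1:A2", "B2:A1", "B3:A0"]
        # breakpoints within +-3 genes (gene spacing 10 kb)
        b1 = segs[1]
        assert abs(b1.start - (20 * 10_000 + 1)) <= 3 * 10_000
        assert abs((segs[2].start - 1) - (49 * 10_000 + 3_000)) <= 3 * 10_000

    def test_cachaco_like_pattern_all_regions_recovered(self, recombined_abb):
        track = cultivar_track(recombined_abb, "allo1")
        report = structure_report(
            track, "ABB", recombined_abb.gene_models, cultivar="allo1"
        )
        found = {
            (s.chromosome, s.label)
            for s in report.deviating_segments
        }
        assert ("chr04", "B1:A2") in found
        assert ("chr04", "B3:A0") in found
        assert ("chr09", "B1:A2") in found
        assert ("chr11", "B3:A0") in found
        # both chr11 ends deviate
        chr11 = [s for s in report.deviating_segments if s.chromosome == "chr11"]
        assert len(chr11) == 2
        # no spurious deviating chromosome
        assert {s.chromosome for s in report.deviating_segments} == {
            "chr04",
            "chr09",
            "chr11",
        }

    def test_segments_tile_without_overlap(self, recombined_abb):
        track = cultivar_track(recombined_abb, "allo1")
        for chrom, sub in track.groupby("chrom"):
            segs = segment_chromosome(sub, 3, gene_models=recombined_abb.gene_models)
            for a, b in zip(segs, segs[1:]):
                assert b.start == a.end + 1

    def test_segment_mean_f_consistent_with_dose(self, recombined_abb):
        # inside a B1:A2 exchange every diagnostic variant sits at 1/3, so
        # the called segment's mean frequency must match (1-eps)*d/P
        track = cultivar_track(recombined_abb, "allo1")
        t4 = track[track["chrom"] == "chr04"]
        segs = segment_chromosome(t4, 3, gene_models=recombined_abb.gene_models)
        b1 = next(s for s in segs if s.label == "B1:A2")
        expected = 0.995 * 1 / 3 + 0.005 * 2 / 3
        se = np.sqrt(expected * (1 - expected) / (90 * b1.n_snps))
        # private-mutation outliers inflate the spread slightly; allow 5 SE
        assert abs(b1.mean_f - expected) < max(5 * se, 0.02)


class TestAneuploidy:
    def test_disomic_chromosome_called(self, recombined_abb):
        track = cultivar_track(recombined_abb, "allo2")
        call = detect_aneuploidy(track[track["chrom"] == "chr08"])
        assert call.ploidy == 2
        assert call.delta_loglik > 0

    def test_trisomic_chromosome_not_called(self, recombined_abb):
        track = cultivar_track(recombined_abb, "allo2")
        call = detect_aneuploidy(track[track["chrom"] == "chr03"])
        assert call.ploidy == 3

    def test_arm_level_detection(self, recombined_abb):
        track = cultivar_track(recombined_abb, "allo2")
        call = detect_aneuploidy(track[track["chrom"] == "chr08"])
        assert call.arm_ploidies.get("p") == 2
        assert call.arm_ploidies.get("q") == 2

    def test_decision_matches_enumeration_oracle(self):
        # ten-window toy: compare against exhaustive per-ploidy likelihood
        # using the same mixture density computed independently
        from allohe.dosage import _site_loglik

        rng = np.random.default_rng(5)
        n = 250
        f = np.where(rng.random(n) < 0.75, 1.0, 0.5)  # disomic B2:A0 signature
        depth = np.full(n, 60)
        alt = rng.binomial(depth, f * 0.99 + 0.005)
        track = _uniform_track(n, alt / depth, depth=60)
        params = SegmentationParams()
        call = detect_aneuploidy(track, params)

        def total(ploidy):
            ll = _site_loglik(
                alt.astype(float),
                depth.astype(float),
                ploidy,
                params.eps,
                params.outlier_fraction,
                params.hemi_fraction,
            )
            return float(ll.max(axis=1).sum())  # best dose per site, uniform track

        expect = 2 if total(2) - total(3) >= params.disomy_delta_loglik else 3
        assert call.ploidy == expect == 2

    def test_too_few_sites_uncallable(self):
        track = _uniform_track(5, 0.5)
        call = detect_aneuploidy(track)
        assert call.uncallable


class TestAnnotateGenes:
    def _segments(self):
        return [
            DosageSegment("chr01", 1, 500_000, 3, 3, 100, 0.99),
            DosageSegment("chr01", 500_001, 993_000, 2, 3, 200, 0.66),
        ]

    def _genes(self):
        rows = [
            ["gA", "chr01", 0, 100_001, 103_000],  # inside B3:A0
            ["gB", "chr01", 1, 600_001, 603_000],  # inside B2:A1
            ["gC", "chr00", 0, 1_000, 4_000],  # unanchored
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "gene_index", "start", "end"])

    def test_midpoint_assignment_and_exclusion(self):
        per_gene, counts = annotate_genes(self._segments(), self._genes())
        a = per_gene.set_index("gene_id")
        assert a.loc["gA", "label"] == "B3:A0"
        assert (a.loc["gA", ["b_dose", "a_dose", "ploidy"]] == [3, 0, 3]).all()
        assert a.loc["gB", "label"] == "B2:A1"
        assert a.loc["gC", "label"] == "unanchored"
        assert counts["n_genes"].sum() == 2  # anchored genes only

    def test_class_counts_percentages(self, recombined_abb):
        track = cultivar_track(recombined_abb, "allo1")
        report = structure_report(
            track, "ABB", recombined_abb.gene_models, cultivar="allo1"
        )
        counts = report.class_counts
        assert counts["n_genes"].sum() == len(recombined_abb.gene_models)
        assert counts["percent"].sum() == pytest.approx(100.0, abs=0.1)
        # designed: 80 genes B3:A0 on chr04+chr11(2x20... 20+30) and 70 B1:A2
        got = counts.set_index("label")["n_genes"]
        assert got["B3:A0"] == pytest.approx(70, abs=8)
        assert got["B1:A2"] == pytest.approx(70, abs=8)


def test_segments_to_bed_coordinates():
    segs = [DosageSegment("chr02", 1, 1000, 2, 3, 50, 0.66)]
    bed = segments_to_bed(segs)
    assert bed.iloc[0]["start"] == 0 and bed.iloc[0]["end"] == 1000
    assert bed.iloc[0]["name"] == "B2:A1"
    assert bed.iloc[0]["score"] == 50
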