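"""CDKN2A exon-1alpha fraction from locus coverage."""

import numpy as np
import pytest

from cdk4prof.cdkn2a_exon_usage import (
    BackgroundModel,
    CoverageTrack,
    LocusAnnotation,
    LocusInterval,
    compute_exon1a,
    corrected_exon_coverage,
    default_annotation,
    exon1a_expression,
    exon1a_fraction,
    fit_intronic_background,
    read_annotation,
    read_coverage,
)
from cdk4prof.synthetic_data import simulate_cdkn2a_coverage


@pytest.fixture
def annotation():
    return LocusAnnotation(
        [
            LocusInterval(0, 100, "intron"),
            LocusInterval(100, 150, "exon1b"),
            LocusInterval(150, 250, "intron"),
            LocusInterval(250, 300, "exon1a"),
            LocusInterval(300, 400, "intron"),
        ]
    )


class TestBackgroundFit:
    def test_constant_background(self, annotation):
        track = CoverageTrack(np.arange(400), np.full(400, 5.0))
        bg = fit_intronic_background(track, annotation)
        assert bg.slope == pytest.approx(0, abs=1e-12)
        assert bg.intercept == pytest.approx(5.0)

    def test_linear_background_recovered(self, annotation):
        pos = np.arange(400)
        track = CoverageTrack(pos, 0.01 * pos + 2.0)
        bg = fit_intronic_background(track, annotation)
        assert bg.slope == pytest.approx(0.01, rel=1e-9)
        assert bg.intercept == pytest.approx(2.0, rel=1e-9)

    def test_all_zero_introns_give_zero_model(self, annotation):
        depth = np.zeros(400)
        depth[250:300] = 10  # exon signal only
        bg = fit_intronic_background(CoverageTrack(np.arange(400), depth), annotation)
        assert bg.slope == 0 and bg.intercept == 0

    def test_too_few_intronic_positions(self):
        ann = LocusAnnotation(
            [
                LocusInterval(0, 1, "intron"),
                LocusInterval(1, 2, "exon1a"),
                LocusInterval(2, 3, "exon1b"),
            ]
        )
        with pytest.raises(ValueError, match="intronic"):
            fit_intronic_background(CoverageTrack(np.arange(3), np.ones(3)), ann)


class TestCorrection:
    def test_clipped_at_zero_when_background_exceeds_depth(self, annotation):
        track = CoverageTrack(np.arange(400), np.full(400, 10.0))
        pos, corr = corrected_exon_coverage(track, annotation, BackgroundModel(0, 15))
        assert (corr == 0).all()

    def test_identity_under_zero_background(self, annotation):
        track = CoverageTrack(np.arange(400), np.full(400, 10.0))
        pos, corr = corrected_exon_coverage(track, annotation, BackgroundModel(0, 0))
        assert (corr == 10).all()

    def test_peak_height_recovered_on_background_line(self, annotation):
        pos = np.arange(400)
        depth = 0.02 * pos + 4.0
        depth[250:300] += 100.0
        track = CoverageTrack(pos, depth)
        res = compute_exon1a(track, annotation)
        assert res.max_cov_exon1a == pytest.approx(100.0, abs=1.0)


class TestFraction:
    def test_arithmetic_and_degenerate_cases(self, annotation):
        pos = np.arange(400)
        corr = np.zeros(400)
        corr[250:300] = 30.0
        corr[100:150] = 70.0
        exon_mask = annotation.mask(pos, "exon1a") | annotation.mask(pos, "exon1b")
        res = exon1a_fraction(pos[exon_mask], corr[exon_mask], annotation)
        assert res.fraction == pytest.approx(0.30)
        # pure p16 transcription
        corr[100:150] = 0.0
        res = exon1a_fraction(pos[exon_mask], corr[exon_mask], annotation)
        assert res.fraction == pytest.approx(1.0)
        # silent locus
        res = exon1a_fraction(pos[exon_mask], np.zeros(exon_mask.sum()), annotation)
        assert res.fraction is None and "silent_locus" in res.flags

    @pytest.mark.parametrize(
        "fraction,cp20m,expected", [(1.0, 80, 80), (0.30, 200, 60), (0.0, 55, 0)]
    )
    def test_expression_scaling(self, fraction, cp20m, expected, annotation):
        from cdk4prof.cdkn2a_exon_usage import Exon1aResult

        res = Exon1aResult("s", 1, 1, fraction)
        assert exon1a_expression(res, cp20m).exon1a_cp20m == pytest.approx(expected)

    def test_undefined_fraction_becomes_zero_with_flag(self):
        from cdk4prof.cdkn2a_exon_usage import Exon1aResult

        res = exon1a_expression(Exon1aResult("s", 0, 0, None), 100.0)
        assert res.exon1a_cp20m == 0
        assert "undefined_fraction_set_to_zero" in res.flags


class TestPipelineProperties:
    def test_noiseless_track_exact(self):
        sim = simulate_cdkn2a_coverage(seed=0, poisson=False)
        res = compute_exon1a(sim.track, sim.annotation)
        assert res.fraction == pytest.approx(sim.true_fraction, abs=1e-12)

    def test_scale_invariance_of_fraction(self):
        sim = simulate_cdkn2a_coverage(seed=1, poisson=False)
        res1 = compute_exon1a(sim.track, sim.annotation)
        scaled = CoverageTrack(sim.track.positions, sim.track.depth * 3.7)
        res2 = compute_exon1a(scaled, sim.annotation)
        assert res1.fraction == pytest.approx(res2.fraction, abs=1e-12)

    def test_idempotence_under_the_model(self):
        """Re-adding the fitted background to the corrected track and
        re-running the pipeline reproduces the same fraction."""
        sim = simulate_cdkn2a_coverage(seed=2)
        bg = fit_intronic_background(sim.track, sim.annotation)
        corrected_all = np.clip(sim.track.depth - bg.predict(sim.track.positions), 0, None)
        rebuilt = CoverageTrack(
            sim.track.positions,
            np.clip(corrected_all + bg.predict(sim.track.positions), 0, None),
        )
        r1 = compute_exon1a(sim.track, sim.annotation)
        r2 = compute_exon1a(rebuilt, sim.annotation)
        assert r2.fraction == pytest.approx(r1.fraction, abs=5e-3)

    def test_poisson_recovery(self):
        errs = []
        for seed in range(25):
            sim = simulate_cdkn2a_coverage(seed=seed)
            res = compute_exon1a(sim.track, sim.annotation)
            errs.append(abs(res.fraction - sim.true_fraction))
        assert np.median(errs) <= 0.02

    def test_zero_exon1a_gives_zero_fraction(self):
        sim = simulate_cdkn2a_coverage(seed=3, h1a=0.0, poisson=False)
        res = compute_exon1a(sim.track, sim.annotation)
        assert res.fraction == pytest.approx(0.0, abs=1e-12)


class TestIO:
    def test_bedgraph_and_tsv_equivalent(self, tmp_path):
        bg = tmp_path / "cov.bedgraph"
        bg.write_text("chr9\t0\t3\t5\nchr9\t3\t5\t7\n")
        tsv = tmp_path / "cov.tsv"
        tsv.write_text("0\t5\n1\t5\n2\t5\n3\t7\n4\t7\n")
        t1, t2 = read_coverage(bg), read_coverage(tsv)
        assert (t1.depth == t2.depth).all()
        assert (t1.positions == t2.positions).all()

    def test_default_annotation_loads(self):
        ann = default_annotation()
        roles = {iv.role for iv in ann.intervals}
        assert {"exon1a", "exon1b", "shared_exon", "intron"} <= roles

    def test_bed4_roles(self, tmp_path):
        bed = tmp_path / "ann.bed"
        bed.write_text("locus\t0\t10\tintron\nlocus\t10\t20\texon1a\nlocus\t20\t30\texon1b\n")
        ann = read_annotation(bed)
        assert ann.mask(np.array([5, 15, 25]), "exon1a").tolist() == [False, True, False]
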