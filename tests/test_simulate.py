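"""Generators: reproducibility and parameter recovery for every stage."""

import math

import numpy as np
import pytest
from scipy import ndimage, stats as sps

from cd4pet import simulate
from cd4pet.decision import growth_responder
from cd4pet.errors import InvalidParameterError
from cd4pet.histology import assign_cells, density_core_margin_score, treg_fraction
from cd4pet.radiometrics import percent_id_per_g
from cd4pet.simulate import (
    PhantomSpec,
    TrialSpec,
    make_cell_pattern,
    make_gamma_dataset,
    make_growth_cohort,
    make_guided_trial,
    make_phantom,
    stage_seed,
)
from cd4pet.spatial import score_volume


class TestReproducibility:
    def test_identical_seeds_identical_outputs(self):
        v1, _, _ = make_phantom(PhantomSpec(pattern="enriched", noise_scale=300, seed=5))
        v2, _, _ = make_phantom(PhantomSpec(pattern="enriched", noise_scale=300, seed=5))
        assert np.array_equal(v1.voxels, v2.voxels)
        t1 = make_guided_trial(TrialSpec(seed=9))
        t2 = make_guided_trial(TrialSpec(seed=9))
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        v1, _, _ = make_phantom(PhantomSpec(noise_scale=300, seed=1))
        v2, _, _ = make_phantom(PhantomSpec(noise_scale=300, seed=2))
        assert not np.array_equal(v1.voxels, v2.voxels)

    def test_stage_seed_derivation(self):
        assert stage_seed(100, "phantom") != stage_seed(100, "trial")
        assert stage_seed(100, "phantom") < 2**31
        with pytest.raises(InvalidParameterError):
            stage_seed(1, "nope")


class TestMakePhantom:
    def test_noiseless_uniform_and_enriched_exact(self):
        for pattern, expected in (("uniform", 1.0), ("enriched", 2.0)):
            volume, tumor, truth = make_phantom(PhantomSpec(pattern=pattern))
            score = score_volume(volume, tumor, truth.ctx, mode="volume3d")
            assert score.ratio == pytest.approx(expected)
            assert score.core_mean == pytest.approx(truth.core_uptake)

    def test_blur_pulls_ratio_toward_one_and_matches_dense_convolution(self):
        spec = PhantomSpec(pattern="enriched", psf_sigma=0.8)
        volume, tumor, truth = make_phantom(spec)
        score = score_volume(volume, tumor, truth.ctx, mode="volume3d")
        assert 1.0 < score.ratio < 2.0
        # oracle: rebuild the unblurred field and convolve densely
        sharp, _, _ = make_phantom(
            PhantomSpec(pattern="enriched", psf_sigma=0.0)
        )
        oracle = ndimage.gaussian_filter(
            sharp.voxels, sigma=[0.8 / s for s in sharp.spacing]
        )
        assert np.allclose(volume.voxels, oracle)

    def test_tumor_must_fit_grid(self):
        with pytest.raises(InvalidParameterError):
            PhantomSpec(tumor_radius=50.0)


class TestMakeGrowthCohort:
    def test_noiseless_labels_recovered_exactly(self):
        cohort = make_growth_cohort(n=40, noise_sigma=0.0, seed=3)
        for sid, curve in cohort.volumes.items():
            assert growth_responder(curve) is cohort.responder_truth[sid]

    def test_zero_responder_fraction(self):
        cohort = make_growth_cohort(n=10, responder_fraction=0.0, seed=1)
        assert not any(cohort.responder_truth.values())

    def test_empirical_fraction_within_binomial_ci(self):
        n, p = 200, 0.55
        cohort = make_growth_cohort(n=n, responder_fraction=p, seed=11)
        k = sum(cohort.responder_truth.values())
        lo, hi = sps.binom.ppf([0.0005, 0.9995], n, p)
        assert lo <= k <= hi


class TestMakeCellPattern:
    def test_zero_densities_empty(self):
        cells, _, _ = make_cell_pattern(
            densities={"core": {"CD4": 0.0}, "margin": {"CD4": 0.0}}, seed=2
        )
        assert cells == []

    def test_density_ratio_recovered_over_seeds(self):
        ratios = []
        dens = {"core": {"CD4": 400.0}, "margin": {"CD4": 200.0}}
        for seed in range(100):
            cells, regions, _ = make_cell_pattern(
                densities=dens, treg_fraction=0.0, seed=seed
            )
            counts = assign_cells(cells, regions)
            ratios.append(
                density_core_margin_score(counts["core"], counts["margin"]).ratio
            )
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_treg_thinning_within_binomial_ci(self):
        cells, regions, _ = make_cell_pattern(
            densities={"core": {"CD4": 800.0}, "margin": {"CD4": 800.0}},
            treg_fraction=0.2,
            seed=4,
        )
        counts = assign_cells(cells, regions)
        cd4 = sum(counts[r].total("CD3+CD8-") for r in ("core", "margin"))
        tregs = sum(counts[r].total("CD4+FoxP3+") for r in ("core", "margin"))
        lo, hi = sps.binom.ppf([0.0005, 0.9995], cd4, 0.2)
        assert lo <= tregs <= hi
        assert 0 < treg_fraction(tregs, cd4) < 1

    def test_homogeneous_pattern_ratio_converges_to_one(self):
        ratios = []
        dens = {"core": {"CD4": 500.0}, "margin": {"CD4": 500.0}}
        for seed in range(100):
            cells, regions, _ = make_cell_pattern(densities=dens, seed=seed)
            counts = assign_cells(cells, regions)
            ratios.append(
                density_core_margin_score(counts["core"], counts["margin"]).ratio
            )
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.03)


class TestMakeGammaDataset:
    def test_exact_round_trip_no_noise(self):
        records, ctx, truth = make_gamma_dataset(
            organ_fractions={"tumor": 0.005, "spleen": 0.02},
            masses={"tumor": 0.5, "spleen": 0.1},
        )
        for rec in records:
            assert percent_id_per_g(rec, ctx) == pytest.approx(
                truth[rec.organ_label], rel=1e-12
            )
        assert truth["tumor"] == pytest.approx(1.0)

    def test_poisson_noise_unbiased(self):
        values = []
        for seed in range(100):
            records, ctx, truth = make_gamma_dataset(
                organ_fractions={"tumor": 0.005},
                masses={"tumor": 0.5},
                poisson_noise=True,
                seed=seed,
            )
            values.append(percent_id_per_g(records[0], ctx))
        assert np.mean(values) == pytest.approx(truth["tumor"], rel=0.02)

    def test_fractions_must_sum_below_one(self):
        with pytest.raises(InvalidParameterError):
            make_gamma_dataset(
                organ_fractions={"a": 0.7, "b": 0.5}, masses={"a": 1.0, "b": 1.0}
            )


class TestMakeGuidedTrial:
    def test_separated_classes_stratify_perfectly(self):
        spec = TrialSpec(
            n_subjects=60, ratio_median_responder=3.0,
            ratio_median_nonresponder=0.5, ratio_sigma=0.05, seed=8,
        )
        trial = make_guided_trial(spec)
        assert (
            (trial["arm"] == "continue_mono") == trial["latent_responder"]
        ).all()

    def test_zero_rescue_keeps_prevalence(self):
        responders = []
        for seed in range(200):
            trial = make_guided_trial(
                TrialSpec(n_subjects=21, rescue_probability=0.0, seed=seed)
            )
            responders.append(trial["responder"].sum())
        total = 200 * 21
        k = sum(responders)
        lo, hi = sps.binom.ppf([0.0005, 0.9995], total, 0.4)
        assert lo <= k <= hi

    def test_expected_mono_fraction_matches_closed_form(self):
        spec = TrialSpec(seed=0)
        fracs = [
            (make_guided_trial(TrialSpec(seed=s))["arm"] == "continue_mono").mean()
            for s in range(200)
        ]
        pi = spec.responder_prevalence
        expected = pi * spec.sensitivity + (1 - pi) * (1 - spec.specificity)
        se = math.sqrt(expected * (1 - expected) / (200 * spec.n_subjects))
        assert np.mean(fracs) == pytest.approx(expected, abs=4 * se)
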