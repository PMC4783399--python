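"""Synthetic cohorts, decline series and virtual tissue sampling."""
import numpy as np
import pytest

from hippocomp import datasets
from hippocomp.age_normalization import fit_decline_exponent
from hippocomp.correspondence import correspondence_analysis, offset_shift
from hippocomp.stereology import fractionator_estimate, gundersen_ce
from hippocomp.synthetic_data import (
    CohortSpec,
    animals_to_frame,
    generate_animals,
    generate_decline_series,
    generate_fractionator_tissue,
    lognormal_from_moments,
)
from hippocomp.transform import CompositionMatrix, scale_matrix


class TestLognormalMomentMatching:
    @pytest.mark.parametrize("mean, sd", [(100.0, 10.0), (5e5, 1e5), (1.0, 2.0)])
    def test_parameters_reproduce_moments(self, mean, sd):
        mu, sigma = lognormal_from_moments(mean, sd)
        got_mean = np.exp(mu + sigma**2 / 2)
        got_var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert got_mean == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(got_var) == pytest.approx(sd, rel=1e-12)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_moments(-1.0, 2.0)


class TestGenerateAnimals:
    def test_same_seed_same_cohort(self):
        spec = CohortSpec.from_fixtures(["dba", "naked_mole_rat"])
        a = animals_to_frame(generate_animals(spec, seed=5))
        b = animals_to_frame(generate_animals(spec, seed=5))
        assert a.equals(b)
        c = animals_to_frame(generate_animals(spec, seed=6))
        assert not a.equals(c)

    def test_cohort_sizes_follow_species_table(self):
        spec = CohortSpec.from_fixtures()
        frame = animals_to_frame(generate_animals(spec, seed=0))
        sizes = frame.groupby("group_id").size()
        assert sizes["c57bl6"] == 13
        assert sizes["bank_vole"] == 4
        assert len(frame) == sum(datasets.group_sizes()[g]
                                 for g in datasets.printed_groups())

    def test_moments_recovered_at_large_n(self):
        spec = CohortSpec.from_fixtures(["naked_mole_rat"])
        spec.n_per_group["naked_mole_rat"] = 10_000
        frame = animals_to_frame(generate_animals(spec, seed=3))
        assert frame["GC"].mean() == pytest.approx(380_255, rel=0.02)
        assert frame["GC"].std(ddof=1) == pytest.approx(34_806, rel=0.05)
        assert frame["HIL"].mean() == pytest.approx(19_365, rel=0.02)

    def test_neurogenesis_markers_attached(self):
        spec = CohortSpec.from_fixtures(["c57bl6"], include_neurogenesis=True)
        frame = animals_to_frame(generate_animals(spec, seed=2))
        assert frame["Ki67"].notna().all()
        assert (frame["DCX"] > 0).all()

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec.from_fixtures(["human"])  # literature-only means


class TestDeclineSeries:
    def test_noiseless_points_lie_on_curve(self):
        ages = np.array([1.0, 3.0, 9.0])
        series = generate_decline_series(-1.2407, 20_000.0, ages, 0.0, seed=0)
        expected = 20_000.0 * (ages / 3.0) ** (-1.2407)
        np.testing.assert_allclose(series["count"], expected, rtol=1e-12)

    def test_fit_on_noiseless_output_roundtrips_exponent(self):
        series = generate_decline_series(-1.0798, 9000.0, [1, 2, 4, 8, 12], 0.0, seed=0)
        model = fit_decline_exponent(series["age_months"], series["count"], "DCX")
        assert model.exponent == pytest.approx(-1.0798, abs=1e-12)

    def test_noisy_fit_within_monte_carlo_tolerance(self):
        rng = np.random.default_rng(13)
        ages = rng.uniform(1.0, 12.0, size=50)
        series = generate_decline_series(-1.2407, 20_000.0, ages, 0.2, seed=99)
        model = fit_decline_exponent(series["age_months"], series["count"], "DCX")
        assert model.exponent == pytest.approx(-1.2407, abs=0.15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_decline_series(-1.0, 100.0, [0.0, 1.0], 0.1, seed=0)
        with pytest.raises(ValueError):
            generate_decline_series(-1.0, 100.0, [1.0], -0.5, seed=0)


class TestFractionatorTissue:
    def test_exhaustive_sampling_counts_every_cell(self):
        sample, true_n = generate_fractionator_tissue(
            500, n_sections=10, section_period=1, frame_side_um=100.0,
            grid_step_um=100.0, disector_height_um=20.0,
            section_thickness_um=20.0, guard_um=0.0, seed=4,
        )
        assert sum(sample.per_section_counts) == true_n
        assert fractionator_estimate(sample) == pytest.approx(true_n)

    def test_empirical_ce_tracks_gundersen_prediction(self):
        """The spread of estimates over replicates should agree with the
        predicted CE to within a modest factor for smooth virtual tissue."""
        estimates, predicted = [], []
        for seed in range(150):
            sample, _ = generate_fractionator_tissue(
                5000, n_sections=60, section_period=3, frame_side_um=40.0,
                seed=seed,
            )
            estimates.append(fractionator_estimate(sample))
            predicted.append(gundersen_ce(sample.per_section_counts).ce)
        empirical_ce = np.std(estimates, ddof=1) / np.mean(estimates)
        assert empirical_ce == pytest.approx(np.mean(predicted), rel=0.3)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            generate_fractionator_tissue(100, n_sections=5, section_period=1,
                                         disector_height_um=25.0,
                                         section_thickness_um=20.0)


class TestPipelineQualitativeStructure:
    def test_mole_rats_separate_from_other_rodents_on_axis1(self):
        """Mole-rat animals sit apart from the rest of the rodent cloud on
        the leading axis, driven by their CA3/HIL imbalance."""
        rodents = [g for g in datasets.printed_groups() if g != "marmoset"]
        spec = CohortSpec.from_fixtures(rodents)
        frame = animals_to_frame(generate_animals(spec, seed=1))
        scaled = scale_matrix(
            CompositionMatrix(frame[list(datasets.POPULATIONS)], semantics="raw")
        )
        result = correspondence_analysis(offset_shift(scaled))
        axis1 = result.row_coords["axis1"]
        is_mole = frame["group_id"].str.contains("mole_rat").to_numpy()
        mole, other = axis1[is_mole], axis1[~is_mole]
        separation = abs(mole.mean() - other.mean())
        spread = max(mole.std(ddof=1), other.std(ddof=1))
        assert separation > spread

    def test_hilus_dominates_axis1_across_available_species(self):
        """On the groups with printed counts the hilus is the strongest
        axis-1 separator and CA3 stays among the leading populations (the
        full published species panel, with primates and other non-rodents,
        is not reconstructible from printed group means)."""
        spec = CohortSpec.from_fixtures()
        frame = animals_to_frame(generate_animals(spec, seed=1))
        scaled = scale_matrix(
            CompositionMatrix(frame[list(datasets.POPULATIONS)], semantics="raw")
        )
        result = correspondence_analysis(offset_shift(scaled))
        contrib = result.col_contrib_pct["axis1"]
        assert contrib.idxmax() == "HIL"
        assert "CA3" in contrib.nlargest(3).index
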