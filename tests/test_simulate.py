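"""Forward simulator: session planning, mixing law, scenarios."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oecpkit import (
    ContactModel,
    default_contact,
    eval_cole_cole,
    generate_study,
    glycerin_water_medium,
    plan_session,
    simulate_acquisition,
    simulate_combination,
)
from oecpkit.simulate import (
    ROLE_AIR_CHECK,
    ROLE_MEDIUM_ONLY,
    ROLE_TOOTH_BARE,
    ROLE_TOOTH_WITH_MEDIUM,
    ROLE_VALIDATION,
)
from oecpkit.variability import repeatability_variation


def exact_contact(w_medium, w_tooth, w_air, seed=0):
    """Deterministic contact: no jitter, no noise."""
    return ContactModel(
        w_medium=w_medium, w_tooth=w_tooth, w_air=w_air,
        weight_jitter_sd=0.0, noise_sd=0.0, seed=seed,
    )


class TestSessionPlan:
    def test_counted_acquisitions_and_composition(self):
        plan = plan_session("crown+G[80]")
        assert len(plan.counted) == 23
        assert plan.role_counts() == {
            ROLE_VALIDATION: 2,
            ROLE_MEDIUM_ONLY: 3,
            ROLE_TOOTH_WITH_MEDIUM: 9,
            ROLE_TOOTH_BARE: 9,
        }

    def test_medium_measured_at_begin_middle_end(self):
        roles = [e.role for e in plan_session("x").entries]
        medium_slots = [i for i, r in enumerate(roles) if r == ROLE_MEDIUM_ONLY]
        with_medium = [i for i, r in enumerate(roles) if r == ROLE_TOOTH_WITH_MEDIUM]
        assert medium_slots[0] < with_medium[0]
        assert with_medium[3] < medium_slots[1] < with_medium[5]
        assert medium_slots[2] > with_medium[-1]

    def test_air_checks_scheduled_but_uncounted(self):
        plan = plan_session("x")
        air = [e for e in plan.entries if e.role == ROLE_AIR_CHECK]
        assert len(air) == 9
        assert all(e not in plan.counted for e in air)

    def test_deterministic_and_scales_to_twelve_combinations(self):
        assert plan_session("a") == plan_session("a")
        total = sum(len(plan_session(f"c{i}").counted) for i in range(12))
        assert total == 276


class TestMixingLaw:
    def test_pure_component_identities(self, grid, make_constant):
        tooth = make_constant(10.0)
        medium = make_constant(40.0)
        pure_medium = simulate_acquisition(tooth, medium, exact_contact(1, 0, 0), 0)
        assert np.allclose(pure_medium.eps_real, 40.0)
        pure_tooth = simulate_acquisition(tooth, medium, exact_contact(0, 1, 0), 0)
        assert np.allclose(pure_tooth.eps_real, 10.0)

    def test_convex_combination(self, make_constant):
        out = simulate_acquisition(
            make_constant(10.0), make_constant(40.0), exact_contact(0.5, 0.5, 0), 0
        )
        assert np.allclose(out.eps_real, 25.0)

    def test_bare_acquisition_reassigns_medium_weight_to_air(self, make_constant):
        out = simulate_acquisition(
            make_constant(10.0), None, exact_contact(0.0, 0.6, 0.4), 0
        )
        assert np.allclose(out.eps_real, 0.6 * 10.0 + 0.4)

    def test_mismatched_grids_rejected(self, make_constant):
        from oecpkit import make_frequency_grid, PermittivitySpectrum

        other = PermittivitySpectrum(
            grid=make_frequency_grid(1e9, 2e9, 5), eps_real=np.full(5, 40.0)
        )
        with pytest.raises(ValueError, match="grids differ"):
            simulate_acquisition(make_constant(10.0), other, exact_contact(0.5, 0.5, 0), 0)

    @given(
        w_medium=st.floats(0, 1),
        w_air=st.floats(0, 1),
        jitter=st.floats(0, 0.2),
        draw=st.integers(0, 50),
    )
    def test_noise_free_output_bounded_by_constituents(
        self, w_medium, w_air, jitter, draw
    ):
        """Conservation: a noise-free acquisition lies between the min and
        max of medium, sample and air permittivities at every frequency."""
        from oecpkit import make_frequency_grid, PermittivitySpectrum

        total = w_medium + w_air
        if total > 1:
            w_medium, w_air = w_medium / total, w_air / total
        w_tooth = max(0.0, 1.0 - w_medium - w_air)
        grid = make_frequency_grid(1e9, 10e9, 31)
        tooth = PermittivitySpectrum(grid=grid, eps_real=np.linspace(11, 9, 31))
        medium = PermittivitySpectrum(grid=grid, eps_real=np.linspace(50, 5, 31))
        contact = ContactModel(
            w_medium=w_medium, w_tooth=w_tooth, w_air=w_air,
            weight_jitter_sd=jitter, noise_sd=0.0, seed=5,
        )
        out = simulate_acquisition(tooth, medium, contact, draw)
        lower = np.minimum(np.minimum(medium.eps_real, tooth.eps_real), 1.0)
        upper = np.maximum(np.maximum(medium.eps_real, tooth.eps_real), 1.0)
        assert np.all(out.eps_real >= lower - 1e-9)
        assert np.all(out.eps_real <= upper + 1e-9)

    def test_more_air_strictly_lowers_the_measurement(self, make_constant):
        tooth, medium = make_constant(10.0), make_constant(40.0)
        less_air = simulate_acquisition(tooth, medium, exact_contact(0.4, 0.5, 0.1), 0)
        more_air = simulate_acquisition(tooth, medium, exact_contact(0.4, 0.3, 0.3), 0)
        assert np.all(more_air.eps_real < less_air.eps_real)


class TestCombination:
    def test_counts_and_determinism(self, crown, contact, bare_contact):
        medium = glycerin_water_medium(0.8)
        a = simulate_combination(crown, medium, contact, bare_contact)
        b = simulate_combination(crown, medium, contact, bare_contact)
        assert len(a.spectra_with_medium) == 9
        assert len(a.spectra_bare) == 9
        assert len(a.spectra_medium_only) == 3
        assert len(a.spectra_validation) == 2
        for sa, sb in zip(a.all_spectra(), b.all_spectra()):
            assert np.array_equal(sa.eps_real, sb.eps_real)

    def test_noise_free_bare_spectra_follow_the_mixing_arithmetic(
        self, make_constant
    ):
        medium = glycerin_water_medium(0.8)
        quiet = exact_contact(0.35, 0.63, 0.02)
        bare = exact_contact(0.0, 0.6, 0.4)
        out = simulate_combination(make_constant(10.0, "t"), medium, quiet, bare)
        for spec in out.spectra_bare:
            assert np.allclose(spec.eps_real, 6.4)

    def test_different_seeds_differ(self, crown, bare_contact):
        medium = glycerin_water_medium(0.8)
        a = simulate_combination(crown, medium, default_contact(1), bare_contact)
        b = simulate_combination(crown, medium, default_contact(2), bare_contact)
        assert not np.array_equal(
            a.spectra_with_medium[0].eps_real, b.spectra_with_medium[0].eps_real
        )


class TestStudyScenarios:
    def test_one_set_per_combination(self, crown, root, catalogue, contact):
        crown_sets = generate_study({"crown": crown}, catalogue, contact)
        assert len(crown_sets) == 12
        root_media = [m for m in catalogue if m.glycerin_fraction >= 0.60]
        root_sets = generate_study({"root": root}, root_media, contact)
        assert len(root_sets) == 9

    def test_unknown_scenario_rejected(self, crown, catalogue, contact):
        with pytest.raises(ValueError, match="unknown scenario"):
            generate_study({"crown": crown}, catalogue, contact, scenario="bogus")

    def test_larger_medium_amount_pulls_toward_the_medium_curve(self, crown, grid):
        medium = [glycerin_water_medium(0.7)]
        quiet = exact_contact(0.35, 0.63, 0.02, seed=3)
        base = generate_study({"crown": crown}, medium, quiet, quiet)[0]
        large = generate_study(
            {"crown": crown}, medium, quiet, quiet, scenario="test_A_large_amount"
        )[0]
        med_curve = eval_cole_cole(medium[0].params, grid).eps_real
        acq_base = base.spectra_with_medium[0].eps_real
        acq_large = large.spectra_with_medium[0].eps_real
        # a larger medium weight moves every point toward the medium side
        shift = acq_large - acq_base
        assert np.all(shift * (med_curve - crown.eps_real) >= -1e-12)
        assert np.abs(acq_large - med_curve).mean() < np.abs(acq_base - med_curve).mean()

    def test_bare_repeats_show_large_range_variation(self, root, contact, bare_contact):
        """Air-gap jitter across bare repeats produces range variation in
        the tens of percent, the behaviour that motivates coupling media."""
        medium = [glycerin_water_medium(0.8)]
        sets = generate_study({"root": root}, medium, contact, bare_contact)
        report = repeatability_variation(sets[0].spectra_bare)
        assert report.average > 10.0

    def test_per_combination_streams_are_independent(self, crown, catalogue, contact):
        sets = generate_study({"crown": crown}, catalogue[:2], contact)
        assert not np.array_equal(
            sets[0].spectra_with_medium[0].eps_real,
            sets[1].spectra_with_medium[0].eps_real,
        )


class TestContactModel:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(w_medium=0.5, w_tooth=0.6, w_air=0.0),
            dict(w_medium=-0.1, w_tooth=1.1, w_air=0.0),
            dict(w_medium=0.5, w_tooth=0.5, w_air=0.0, noise_sd=-1),
            dict(w_medium=0.5, w_tooth=0.5, w_air=0.0, seed=-1),
        ],
    )
    def test_invalid_contacts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContactModel(**kwargs)

    def test_weights_must_sum_to_one_within_tolerance(self):
        ContactModel(w_medium=0.2, w_tooth=0.5, w_air=0.3)  # exact
        with pytest.raises(ValueError, match="sum to 1"):
            ContactModel(w_medium=0.2, w_tooth=0.5, w_air=0.301)
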