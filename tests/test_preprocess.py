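"""Preprocessing: Savitzky-Golay smoothing, region trimming/merging, the
contact-area statistic, repeat/location exclusion, and coefficient of
variation."""

import numpy as np
import pytest

from nirscart.preprocess import (
    ContactQualityScore,
    coefficient_of_variation,
    contact_area,
    contamination_threshold,
    flag_contaminated_location,
    preprocess_for,
    select_best_spectra,
    sg_smooth,
    arthroscopic_qc,
)
from nirscart.study import (
    ARM_A_GRID,
    ARM_B_GRID,
    AcquisitionConfig,
    AcquisitionContext,
    LatentTissueState,
    RawSpectrum,
    StudyDesign,
    generate_study,
    simulate_spectrum,
)

STATE = LatentTissueState(0.72, 1.0, 1.0, 1.0, 0.5)


def _raw(arm_a=None, arm_b=None, repeat_index=0):
    return RawSpectrum(
        arm_a_wavelengths=ARM_A_GRID.copy(),
        arm_a_intensity=np.ones(ARM_A_GRID.size) if arm_a is None else arm_a,
        arm_b_wavelengths=ARM_B_GRID.copy(),
        arm_b_intensity=np.ones(ARM_B_GRID.size) if arm_b is None else arm_b,
        metadata={"repeat_index": repeat_index},
    )


class TestSgSmooth:
    def test_constant_preserved(self):
        x = np.full(200, 3.7)
        assert np.allclose(sg_smooth(x, 13), x)

    def test_cubic_preserved_on_interior(self):
        t = np.linspace(-1, 1, 300)
        y = 0.3 * t**3 - 1.2 * t**2 + t + 4
        sm = sg_smooth(y, 25)
        assert np.allclose(sm[12:-12], y[12:-12], atol=1e-9)

    def test_matches_per_window_polyfit_oracle(self, rng):
        """Interior output equals the centre of a cubic least-squares fit
        over the moving window."""
        y = rng.normal(size=80)
        window, half = 13, 6
        sm = sg_smooth(y, window)
        t = np.arange(window) - half
        for i in range(half, y.size - half):
            coef = np.polyfit(t, y[i - half : i + half + 1], 3)
            assert sm[i] == pytest.approx(np.polyval(coef, 0.0), abs=1e-9)

    @pytest.mark.parametrize("window", [12, 3, 9999])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            sg_smooth(np.ones(100), window)


class TestPreprocessFor:
    @pytest.mark.parametrize(
        "family,windows", [("cartilage", (25, 13)), ("bone", (45, 13))]
    )
    def test_windows_recorded_per_family(self, family, windows):
        proc = preprocess_for(family, _raw())
        assert proc.windows == windows
        assert proc.variant == family

    def test_region_trimming_contract(self):
        proc = preprocess_for("cartilage", _raw(), region=(0.75, 1.90))
        assert proc.wavelengths.min() >= 0.75
        assert proc.wavelengths.max() < 1.90

    def test_no_saturated_channels_ever(self):
        proc = preprocess_for("bone", _raw())
        assert np.all(proc.wavelengths < 1.90)

    def test_arm_merge_single_channel_per_wavelength(self):
        proc = preprocess_for("cartilage", _raw())
        assert np.all(np.diff(proc.wavelengths) > 0)
        # arm A contributes below 1.0 um, arm B from 1.0 um
        assert np.sum((proc.wavelengths >= 1.0) & (proc.wavelengths < 1.1)) == np.sum(
            (ARM_B_GRID >= 1.0) & (ARM_B_GRID < 1.1)
        )

    def test_trim_idempotent(self):
        proc = preprocess_for("cartilage", _raw())
        once = proc.trim((0.75, 1.90))
        twice = once.trim((0.75, 1.90))
        assert np.array_equal(once.wavelengths, twice.wavelengths)
        assert np.array_equal(once.intensity, twice.intensity)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            preprocess_for("tendon", _raw())


class TestContactArea:
    def test_linear_spectrum_gives_zero(self):
        arm_a = 2.0 - 0.5 * ARM_A_GRID
        score = contact_area(_raw(arm_a=arm_a), smooth_window=None)
        assert score.area == pytest.approx(0.0, abs=1e-12)

    def test_triangular_bump_area(self):
        """A triangular deviation of height h and base W on top of the
        endpoint line integrates to h*W/2 (trapezoid oracle)."""
        h, centre, half = 0.2, 0.585, 0.1
        base = np.full(ARM_A_GRID.size, 1.0)
        tri = np.clip(h * (1 - np.abs(ARM_A_GRID - centre) / half), 0, None)
        score = contact_area(_raw(arm_a=base + tri), smooth_window=None)
        assert score.area == pytest.approx(h * 2 * half / 2, rel=1e-3)

    def test_smoothed_variant_close_to_oracle(self):
        h, centre, half = 0.2, 0.585, 0.1
        tri = np.clip(h * (1 - np.abs(ARM_A_GRID - centre) / half), 0, None)
        score = contact_area(_raw(arm_a=1.0 + tri))
        assert score.area == pytest.approx(h * half, rel=0.02)

    def test_doubling_deviation_doubles_area(self, rng):
        dev = np.abs(np.sin(ARM_A_GRID * 40)) * 0.05
        a1 = contact_area(_raw(arm_a=1.0 + dev), smooth_window=None).area
        a2 = contact_area(_raw(arm_a=1.0 + 2 * dev), smooth_window=None).area
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_region_not_covered_rejected(self):
        raw = _raw()
        raw.arm_a_wavelengths = raw.arm_a_wavelengths + 0.5
        with pytest.raises(ValueError):
            contact_area(raw)


class TestSelectBestSpectra:
    def test_retains_smallest_areas(self):
        scores = [ContactQualityScore(float(a), repeat_index=i)
                  for i, a in enumerate(np.arange(15, 0, -1))]
        kept = select_best_spectra(scores, keep=8)
        assert sorted(s.area for s in kept) == list(map(float, range(1, 9)))

    def test_tie_break_by_repeat_index(self):
        scores = [ContactQualityScore(1.0, repeat_index=i) for i in range(15)]
        kept = select_best_spectra(scores, keep=8)
        assert sorted(s.repeat_index for s in kept) == list(range(8))

    def test_fifteen_in_eight_out(self):
        scores = [ContactQualityScore(float(i), repeat_index=i) for i in range(15)]
        assert len(select_best_spectra(scores)) == 8

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            select_best_spectra([ContactQualityScore(1.0)] * 5, keep=8)

    def test_permutation_invariant(self, rng):
        scores = [ContactQualityScore(float(a), repeat_index=i)
                  for i, a in enumerate(rng.uniform(size=15))]
        kept1 = {s.repeat_index for s in select_best_spectra(scores)}
        perm = [scores[i] for i in rng.permutation(15)]
        kept2 = {s.repeat_index for s in select_best_spectra(perm)}
        assert kept1 == kept2


class TestContaminationFlag:
    def test_clean_location_not_flagged(self, rng):
        ctx = AcquisitionContext("arthroscopic", contact_quality=1.0,
                                 arthroscope_light_level=0.0)
        scores = [
            contact_area(simulate_spectrum(STATE, ctx, rng)) for _ in range(8)
        ]
        inv = [
            contact_area(
                simulate_spectrum(STATE, AcquisitionContext("in_vitro"), rng)
            ).area
            for _ in range(30)
        ]
        thr = contamination_threshold(np.array(inv))
        assert flag_contaminated_location(scores, thr) is False

    def test_strong_light_flagged(self, rng):
        """Light at 10x the band-depth scale trips the in-vitro-derived
        threshold (generator and statistic exercised end to end)."""
        ctx = AcquisitionContext("arthroscopic", contact_quality=0.9,
                                 arthroscope_light_level=1.0)
        scores = [
            contact_area(simulate_spectrum(STATE, ctx, rng)) for _ in range(8)
        ]
        inv = [
            contact_area(
                simulate_spectrum(STATE, AcquisitionContext("in_vitro"), rng)
            ).area
            for _ in range(30)
        ]
        thr = contamination_threshold(np.array(inv))
        assert flag_contaminated_location(scores, thr) is True

    def test_infinite_threshold_never_flags(self, rng):
        ctx = AcquisitionContext("arthroscopic", arthroscope_light_level=0.5)
        scores = [contact_area(simulate_spectrum(STATE, ctx, rng)) for _ in range(8)]
        assert flag_contaminated_location(scores, np.inf) is False

    def test_area_increases_with_light_level(self, rng):
        """Mean contact area is strictly increasing over a 4-point light
        grid on generator data."""
        means = []
        for level in (0.0, 0.02, 0.1, 0.4):
            ctx = AcquisitionContext(
                "arthroscopic", arthroscope_light_level=level, noise_sd=0.003
            )
            areas = [
                contact_area(simulate_spectrum(STATE, ctx, rng)).area
                for _ in range(25)
            ]
            means.append(np.mean(areas))
        assert np.all(np.diff(means) > 0)


class TestCoefficientOfVariation:
    def _proc(self, scale=1.0):
        raw = simulate_spectrum(
            STATE, AcquisitionContext("in_vitro", noise_sd=0.0),
            np.random.default_rng(0),
        )
        raw.arm_a_intensity = raw.arm_a_intensity * scale
        raw.arm_b_intensity = raw.arm_b_intensity * scale
        return preprocess_for("cartilage", raw, region=(0.75, 1.90))

    def test_identical_spectra_zero(self):
        assert coefficient_of_variation(self._proc(), self._proc()) == pytest.approx(0.0)

    def test_two_percent_offset_closed_form(self):
        """x vs 1.02x per channel: population SD/mean = 0.01/1.01."""
        cv = coefficient_of_variation(self._proc(), self._proc(1.02))
        assert cv == pytest.approx(100 * 0.01 / 1.01, rel=1e-6)

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(self._proc(), self._proc(), region=(2.0, 2.4))


def test_qc_excludes_contaminated_locations_and_keeps_eight():
    design = StudyDesign(
        n_repair_ponies=2, n_control_ponies=1, joints_per_pony=1,
        locations_per_joint=4, n_unreachable=0, seed=21,
    )
    acq = AcquisitionConfig(
        contaminated_locations=frozenset({(0, 0, 1)}),
        contaminated_light_level=0.05,
    )
    study = generate_study(design, acquisition=acq)
    retained, qc = arthroscopic_qc(study.arthro, study.invitro)
    assert qc["flagged"].sum() == 1
    assert qc.loc[qc["flagged"], "location"].tolist() == [1]
    counts = retained.meta.groupby(["pony", "joint", "location"]).size()
    assert (counts == 8).all()
    assert len(counts) == 7  # 8 repair locations minus the flagged one
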