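"""Generator contracts: serum composition, matrix effects, noise, masking."""

import math
from fractions import Fraction

import numpy as np
import pytest

import nabtiter as nt
from nabtiter.simulate import MASKING_SAMPLE, masking_demo_truth

from conftest import curve_by_sample


class TestSerumComposition:
    def test_csc_total_serum_constant_across_dilutions(self, csc_design):
        for d in (Fraction(1, 4), Fraction(1, 128)):
            assert nt.serum_composition("CSC", d, csc_design) == pytest.approx(0.10)

    def test_vsc_limit_of_no_test_serum_is_medium_serum(self, vsc_design):
        assert nt.serum_composition("VSC", 1e-12, vsc_design) == pytest.approx(
            vsc_design.vsc_medium_serum
        )

    def test_vsc_strictly_increases_with_serum_content(self, vsc_design):
        s_quarter = nt.serum_composition("VSC", Fraction(1, 4), vsc_design)
        s_128 = nt.serum_composition("VSC", Fraction(1, 128), vsc_design)
        assert s_quarter > s_128

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_dilution_outside_unit_interval_rejected(self, bad, csc_design):
        with pytest.raises(ValueError):
            nt.serum_composition("CSC", bad, csc_design)


class TestMatrixEffectModel:
    def test_enhancement_monotone_and_unity_at_zero(self):
        m = nt.MatrixEffectModel(enhance_amplitude=2.0, enhance_halfsat=0.05)
        s = np.linspace(0, 0.5, 50)
        e = m.enhancement(s)
        assert e[0] == pytest.approx(1.0)
        assert np.all(np.diff(e) >= 0)

    def test_inhibition_monotone_and_unity_at_zero(self):
        m = nt.MatrixEffectModel(inhibit_strength=8.0, inhibit_shape=1.0)
        s = np.linspace(0, 0.5, 50)
        i = m.inhibition(s)
        assert i[0] == pytest.approx(1.0)
        assert np.all(np.diff(i) <= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            nt.MatrixEffectModel(enhance_amplitude=-1)
        with pytest.raises(ValueError):
            nt.MatrixEffectModel(inhibit_shape=0)


class TestSimulatePlate:
    def test_seronegative_csc_noisefree_is_exactly_100(self, noisefree_csc_curves):
        curve = curve_by_sample(noisefree_csc_curves, "neg")
        # matrix factor cancels against the format-matched control
        for p in curve.points:
            assert p.mean_pct == pytest.approx(100.0, abs=1e-9)

    def test_seronegative_vsc_noisefree_inflated_and_increasing(
        self, seroneg_profile, vsc_design
    ):
        truth = nt.SimulationTruth(profiles=(seroneg_profile,), design=vsc_design)
        curve = nt.normalize_plate(nt.simulate_plate(truth))[0]
        vals = [p.mean_pct for p in curve.points]  # 1/128 ... 1/4
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 100.0

    def test_seropositive_csc_hits_50_at_true_nd50(self, csc_design):
        profile = nt.SampleProfile("pos", true_nd50=Fraction(1, 16), hill_slope=2.0)
        truth = nt.SimulationTruth(profiles=(profile,), design=csc_design)
        curve = nt.normalize_plate(nt.simulate_plate(truth))[0]
        assert curve.point_at(Fraction(1, 16)).mean_pct == pytest.approx(50.0)

    def test_determinism_byte_identical_given_seed(self, seropos_profile):
        design = nt.AssayDesign(format="VSC", noise_sigma=0.05, seed=7)
        truth = nt.SimulationTruth(profiles=(seropos_profile,), design=design)
        a = nt.simulate_plate(truth)
        b = nt.simulate_plate(truth)
        assert a.wells == b.wells

    def test_every_well_traceable_to_profile_or_control(self, seropos_profile):
        truth = nt.SimulationTruth(profiles=(seropos_profile,))
        plates = nt.simulate_plate(truth)
        ids = {w.sample_id for w in plates.wells}
        assert ids == {"pos", "control"}
        for w in plates.wells:
            if w.sample_id == "control":
                assert w.role == "antibody_free_control"

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            nt.AssayDesign(baseline_rlu=0.0)

    def test_empty_dilution_list_rejected(self):
        with pytest.raises(ValueError):
            nt.AssayDesign(dilutions=())

    def test_noise_log_sd_converges_to_noise_sigma(self):
        # 10^4 replicates of one well condition; sample SD of log RLU
        # within 5% of the generator's noise_sigma
        design = nt.AssayDesign(
            format="CSC",
            dilutions=(Fraction(1, 4), Fraction(1, 8)),
            replicates=10_000,
            noise_sigma=0.05,
            seed=11,
        )
        truth = nt.SimulationTruth(
            profiles=(nt.SampleProfile("neg"),), design=design
        )
        plates = nt.simulate_plate(truth)
        logs = [
            math.log(w.rlu)
            for w in plates.wells
            if w.role == "test" and w.dilution == Fraction(1, 4)
        ]
        assert len(logs) == 10_000
        assert np.std(logs, ddof=1) == pytest.approx(0.05, rel=0.05)


class TestSerumTitration:
    def test_self_normalization_at_zero_serum(self):
        df = nt.simulate_serum_titration("on_aav", [0.0, 0.05], replicates=2)
        at_zero = df.loc[df.serum_level == 0.0, "transduction_pct"]
        assert np.allclose(at_zero, 100.0)

    def test_on_aav_noisefree_monotone_enhancement(self):
        df = nt.simulate_serum_titration("on_aav", [0.0, 0.01, 0.05, 0.10])
        means = df.groupby("serum_level")["transduction_pct"].mean()
        assert np.all(np.diff(means.values) >= 0)
        assert np.all(means.values >= 100.0 - 1e-9)

    def test_on_cells_noisefree_monotone_inhibition(self):
        df = nt.simulate_serum_titration("on_cells", [0.0, 0.01, 0.05, 0.10])
        means = df.groupby("serum_level")["transduction_pct"].mean()
        assert np.all(np.diff(means.values) <= 0)
        assert np.all(means.values <= 100.0 + 1e-9)

    def test_missing_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="0%"):
            nt.simulate_serum_titration("on_aav", [0.05, 0.10])


class TestMaskingScenario:
    """Documented parameter set where VSC baseline inflation hides a titer."""

    def test_masked_sample_visible_under_csc_only(self):
        csc = nt.normalize_plate(nt.simulate_plate(masking_demo_truth("CSC")))
        vsc = nt.normalize_plate(nt.simulate_plate(masking_demo_truth("VSC")))
        c = curve_by_sample(csc, MASKING_SAMPLE.sample_id)
        v = curve_by_sample(vsc, MASKING_SAMPLE.sample_id)
        assert min(p.mean_pct for p in v.points) > 50.0
        assert min(p.mean_pct for p in c.points) < 50.0

    def test_truth_sidecar_roundtrip(self, tmp_path):
        truth = masking_demo_truth("VSC")
        truth.to_yaml(tmp_path / "truth.yaml")
        back = nt.SimulationTruth.from_yaml(tmp_path / "truth.yaml")
        assert back == truth
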