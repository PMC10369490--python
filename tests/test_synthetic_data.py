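"""Generator contracts: known ground truth in, statistically faithful data out."""

import numpy as np
import pandas as pd
import pytest

from pkamem import synthetic_data as syn
from pkamem._utils import hill_protonation


class TestGroundTruthProfile:
    def test_interpolation_and_clamping(self):
        p = syn.GroundTruthProfile.linear((-6.0, 0.0), (7.0, 6.0))
        assert p.pka_at(-6.0) == 7.0
        assert p.pka_at(0.0) == 6.0
        assert p.pka_at(-3.0) == pytest.approx(6.5)
        # outside the covered range the terminal value is held
        assert p.pka_at(-10.0) == 7.0
        assert p.pka_at(3.0) == 6.0

    def test_validation(self):
        with pytest.raises(ValueError):
            syn.GroundTruthProfile(np.array([0.0, 0.0]), np.array([6.0, 6.0]))
        with pytest.raises(ValueError):
            syn.GroundTruthProfile(np.array([0.0, 1.0]), np.array([6.0, np.inf]))
        with pytest.raises(ValueError):
            syn.GroundTruthProfile(np.array([0.0, 1.0]), np.array([6.0, 6.0]), hill_n=-1)


class TestBilayer:
    def test_flat_leaflets_sit_at_half_thickness(self):
        bl = syn.generate_bilayer(64, 19.0, seed=1, z_noise=0.2)
        assert np.all(np.abs(bl.upper[:, 2] - 19.0) < 1.5)
        assert np.all(np.abs(bl.lower[:, 2] + 19.0) < 1.5)
        assert abs(bl.upper[:, 2].mean() - 19.0) < 0.15
        assert abs(bl.lower[:, 2].mean() + 19.0) < 0.15

    def test_gaussian_dimple_depth_at_center(self):
        # amplitude −3 Å at the box center: minimum leaflet z ≈ 19 − 3 = 16 Å
        bl = syn.generate_bilayer(
            256,
            19.0,
            syn.GaussianDimple(-3.0, 8.0, center=(64.0, 64.0)),
            seed=2,
            z_noise=0.1,
            atoms_per_lipid=3,
        )
        assert bl.upper[:, 2].min() == pytest.approx(16.0, abs=0.6)
        # lower leaflet untouched by an upper-leaflet field
        assert bl.lower[:, 2].min() == pytest.approx(-19.0, abs=0.6)

    def test_same_seed_bitwise_identical(self):
        a = syn.generate_bilayer(32, 19.0, seed=7)
        b = syn.generate_bilayer(32, 19.0, seed=7)
        assert np.array_equal(a.upper, b.upper) and np.array_equal(a.lower, b.lower)

    @pytest.mark.parametrize("kwargs", [dict(n_lipids_per_leaflet=8), dict(half_thickness=0.0)])
    def test_invalid_parameters(self, kwargs):
        base = dict(n_lipids_per_leaflet=32, half_thickness=19.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            syn.generate_bilayer(**base)

    def test_gro_export_roundtrip_units(self, tmp_path):
        bl = syn.generate_bilayer(16, 19.0, seed=3)
        path = tmp_path / "bilayer.gro"
        bl.to_gro(path)
        lines = path.read_text().splitlines()
        assert int(lines[1]) == 32
        z_nm = float(lines[2][36:44])
        assert abs(abs(z_nm) - 1.9) < 0.2  # Å -> nm conversion


class TestPhreFrames:
    def test_flat_profile_logistic_fractions(self):
        # pKa 6.0, n=1: protonated fraction 0.909 at pH 5 and 0.091 at pH 7
        profile = syn.GroundTruthProfile.linear((-6.0, 0.0), (6.0, 6.0))
        cfg = syn.SyntheticConfig(
            n_replicates=1, ph_ladder=(5.0, 7.0), n_frames=10000, seed=4
        )
        frames = syn.generate_phre_frames(profile, cfg)
        for ph, expected in ((5.0, 1 / (1 + 10 ** (5.0 - 6.0))), (7.0, 1 / (1 + 10 ** (7.0 - 6.0)))):
            frac = frames.loc[frames.ph == ph, "prot_asp"].mean()
            tol = 4 * np.sqrt(expected * (1 - expected) / 10000)
            assert abs(frac - expected) < tol

    def test_midpoint_gives_half_protonation(self):
        profile = syn.GroundTruthProfile.linear((-6.0, 0.0), (6.0, 6.0), hill_n=2.5)
        cfg = syn.SyntheticConfig(n_replicates=1, ph_ladder=(6.0,), n_frames=20000, seed=4)
        frames = syn.generate_phre_frames(profile, cfg)
        assert frames["prot_asp"].mean() == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(20000))

    def test_zero_frames_gives_empty_stream(self):
        profile = syn.GroundTruthProfile.linear()
        frames = syn.generate_phre_frames(profile, syn.SyntheticConfig(n_frames=0))
        assert frames.empty

    def test_empty_ladder_rejected(self):
        with pytest.raises(ValueError):
            syn.SyntheticConfig(ph_ladder=())

    def test_depth_bounds_respected_and_deterministic(self):
        profile = syn.GroundTruthProfile.linear()
        cfg = syn.SyntheticConfig(n_frames=2000, seed=9, depth_bounds=(-5.0, 1.0))
        a = syn.generate_phre_frames(profile, cfg)
        b = syn.generate_phre_frames(profile, cfg)
        assert a.equals(b)
        assert a["insertion_A"].between(-5.0, 1.0).all()
        # every (replicate, replica) pair is present
        assert a.groupby(["replicate", "replica"]).ngroups == 5 * 4


class TestContactProfiles:
    def test_zero_dispersion_is_deterministic(self):
        depths = np.linspace(-5, 0, 50)
        out = syn.generate_contact_profiles(depths, {"n_phos": lambda z: 3.0 + 0 * z}, 0.0)
        assert (out["n_phos"] == 3).all()

    def test_poisson_channel_mean(self):
        depths = np.zeros(10000)
        out = syn.generate_contact_profiles(depths, {"n_chol": lambda z: 5.0 + 0 * z}, 1.0, seed=6)
        assert out["n_chol"].mean() == pytest.approx(5.0, abs=4 * np.sqrt(5.0 / 10000))
        assert (out["n_chol"] >= 0).all()

    def test_undefined_mean_raises(self):
        with pytest.raises(ValueError):
            syn.generate_contact_profiles(
                np.array([-1.0, 1.0]), {"n_phos": lambda z: np.where(z > 0, np.nan, 1.0)}, 1.0
            )

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_contact_profiles(np.zeros(3), {"n_phos": lambda z: 1.0 + 0 * z}, -1.0)


class TestTitrationGenerator:
    def test_midpoint_response(self):
        out = syn.generate_titration_experiment(6.0, 1.5, 0.2, 0.6, 0.0, [6.0])
        assert out["response"].iloc[0] == pytest.approx(0.2 + 0.3)

    def test_large_n_approaches_step(self):
        out = syn.generate_titration_experiment(6.0, 80.0, 0.0, 1.0, 0.0, [5.5, 6.5])
        assert out["response"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert out["response"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            syn.generate_titration_experiment(6.0, 1.0, 0.0, 0.0, 0.0, [5, 6, 7])
        with pytest.raises(ValueError):
            syn.generate_titration_experiment(6.0, 1.0, 0.0, 1.0, 0.0, [])


class TestKineticGenerator:
    def test_single_term_at_time_zero(self):
        out = syn.generate_kinetic_trace([1.0], [0.1], 0.0, [0.0], offset=0.25)
        assert out["intensity"].iloc[0] == pytest.approx(1.25)

    def test_long_time_limit_is_offset(self):
        out = syn.generate_kinetic_trace([1.0, 0.5], [0.1, 0.4], 0.0, [1e6], offset=0.3)
        assert out["intensity"].iloc[0] == pytest.approx(0.3, abs=1e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_kinetic_trace([1.0], [0.0], 0.0, [0.0, 1.0])


def test_named_substreams_are_independent():
    """Adding a channel must not perturb the draws of another channel."""
    depths = np.zeros(500)
    only = syn.generate_contact_profiles(depths, {"n_phos": lambda z: 2.0 + 0 * z}, 1.0, seed=11)
    both = syn.generate_contact_profiles(
        depths,
        {"n_phos": lambda z: 2.0 + 0 * z, "n_chol": lambda z: 1.0 + 0 * z},
        1.0,
        seed=11,
    )
    assert only["n_phos"].equals(both["n_phos"])
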