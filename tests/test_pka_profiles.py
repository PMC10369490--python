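"""Insertion slicing, criteria screening, Hill fits and bootstrap errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkamem import pka_profiles as pk
from pkamem import synthetic_data as syn
from pkamem._utils import hill_protonation

from conftest import make_criteria_frames

LADDER = (5.0, 5.75, 6.5, 7.25)


def balanced_cells(n_prot_by_ph, n=40):
    """Cells for 5 replicates x 4 replicas with identical per-pH fractions."""
    out = {}
    for rep in range(5):
        for replica, ph in enumerate(LADDER):
            out.setdefault((rep, replica), {})[ph] = (n_prot_by_ph[ph], n - n_prot_by_ph[ph])
    return out


def exact_curve(pka, n_hill=1.0, n_frames=400):
    """TitrationCurve whose cell means equal the exact logistic values."""
    rows = []
    for rep in range(5):
        for replica, ph in enumerate(LADDER):
            rows.append(
                dict(
                    replicate=rep,
                    replica=replica,
                    ph=ph,
                    n_frames=n_frames,
                    n_prot=int(round(n_frames * hill_protonation(ph, pka, n_hill))),
                    mean_prot=hill_protonation(ph, pka, n_hill),
                )
            )
    cells = pd.DataFrame(rows)
    pooled = cells.groupby("ph")["mean_prot"].mean().sort_index()
    return pk.TitrationCurve(
        cells=cells,
        ph_values=pooled.index.to_numpy(),
        mean_protonation=pooled.to_numpy(),
    )


class TestSlicing:
    def test_half_open_bin_assignment(self):
        assert pk.InsertionBin.of(-2.3) == pk.InsertionBin(-2.5, -2.0)
        assert pk.InsertionBin.of(-2.0) == pk.InsertionBin(-2.0, -1.5)
        assert -2.0 in pk.InsertionBin(-2.0, -1.5)
        assert -2.0 not in pk.InsertionBin(-2.5, -2.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=500))
    def test_partition_property(self, n):
        rng = np.random.default_rng(n)
        frames = pd.DataFrame(
            {
                "insertion_A": rng.uniform(-8, 2, n),
                "replicate": 0,
                "replica": 0,
                "ph": 6.0,
                "prot_asp": 0,
                "time_ps": np.arange(n, dtype=float),
            }
        )
        sliced = pk.slice_by_insertion(frames)
        assert sum(len(v) for v in sliced.values()) == n
        for b, sub in sliced.items():
            assert sub["insertion_A"].between(b.lower, b.upper, inclusive="left").all()


class TestCriteria:
    def test_undersized_state_cell_fails_criterion_one(self):
        cells = balanced_cells({5.0: 20, 5.75: 18, 6.5: 12, 7.25: 10})
        cells[(0, 0)][5.0] = (9, 31)  # nine protonated points in one cell
        ledger = pk.check_criteria(make_criteria_frames(cells))
        assert not ledger.c1_state_counts
        assert ledger.c2_replicate_coverage and ledger.c3_monotonic
        assert ledger.diagnostics["c1_undersized_cells"][0]["n_prot"] == 9

    def test_too_few_replicates_fails_criterion_two(self):
        cells = balanced_cells({5.0: 20, 5.75: 18, 6.5: 12, 7.25: 10})
        cells = {k: v for k, v in cells.items() if k[0] < 2}  # two replicates only
        ledger = pk.check_criteria(make_criteria_frames(cells))
        assert not ledger.c2_replicate_coverage
        assert ledger.c1_state_counts and ledger.c3_monotonic

    def test_single_replica_replicate_fails_criterion_two(self):
        cells = balanced_cells({5.0: 20, 5.75: 18, 6.5: 12, 7.25: 10})
        cells = {k: v for k, v in cells.items() if k[0] != 0 or k[1] == 0}
        ledger = pk.check_criteria(make_criteria_frames(cells))
        assert not ledger.c2_replicate_coverage

    def test_rising_titration_curve_fails_criterion_three(self):
        # protonation 0.40 at pH 5.75 but 0.46 at pH 6.50: rise of 0.06 > 0.05
        cells = balanced_cells({5.0: 25, 5.75: 20, 6.5: 23, 7.25: 10}, n=50)
        ledger = pk.check_criteria(make_criteria_frames(cells))
        assert not ledger.c3_monotonic
        assert ledger.diagnostics["c3_violating_ph"] == [6.5]
        assert ledger.c1_state_counts and ledger.c2_replicate_coverage

    def test_conforming_bin_passes_all(self):
        cells = balanced_cells({5.0: 30, 5.75: 24, 6.5: 16, 7.25: 10})
        ledger = pk.check_criteria(make_criteria_frames(cells))
        assert ledger.all_passed

    def test_screen_is_order_independent_and_idempotent(self):
        cells = balanced_cells({5.0: 30, 5.75: 24, 6.5: 16, 7.25: 10})
        frames = make_criteria_frames(cells)
        shuffled = frames.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = pk.check_criteria(frames)
        b = pk.check_criteria(shuffled)
        assert a.as_dict() == b.as_dict() == pk.check_criteria(shuffled).as_dict()

    def test_removing_frames_cannot_rescue_criterion_one(self):
        cells = balanced_cells({5.0: 20, 5.75: 18, 6.5: 12, 7.25: 10})
        cells[(0, 0)][5.0] = (9, 31)
        frames = make_criteria_frames(cells)
        rng = np.random.default_rng(0)
        # drop a strict subset of every cell (cells stay populated)
        keep = frames.groupby(["replicate", "ph"], group_keys=False).apply(
            lambda g: g.sample(frac=0.8, random_state=rng.integers(2**31)),
            include_groups=False,
        )
        keep = frames.loc[keep.index]
        assert not pk.check_criteria(keep).c1_state_counts


class TestFit:
    def test_exact_logistic_recovery(self):
        pka, n, ok = pk.fit_pka(exact_curve(6.0, 1.0))
        assert ok
        assert pka == pytest.approx(6.0, abs=1e-6)
        assert n == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_ph_is_pka(self):
        curve = exact_curve(5.75, 1.3)
        pka, _, _ = pk.fit_pka(curve)
        assert pka == pytest.approx(5.75, abs=1e-6)

    def test_fixed_hill_coefficient_mode(self):
        pka, n, ok = pk.fit_pka(exact_curve(6.3, 1.0), fix_hill_n=1.0)
        assert ok and n == 1.0
        assert pka == pytest.approx(6.3, abs=1e-6)

    def test_too_few_ph_points_rejected(self):
        curve = exact_curve(6.0)
        with pytest.raises(ValueError):
            pk.fit_pka(curve, drop_ph=(5.0, 5.75))


class TestBayesianBootstrap:
    def test_degenerate_identical_samples_give_zero_sd(self):
        sd, discarded = pk.bayesian_bootstrap_sd(exact_curve(6.0), n_boot=200, seed=0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_seed_reproducibility(self):
        curve = exact_curve(6.0)
        noisy = curve.cells.copy()
        rng = np.random.default_rng(3)
        noisy["mean_prot"] = np.clip(noisy["mean_prot"] + rng.normal(0, 0.02, len(noisy)), 0, 1)
        pooled = noisy.groupby("ph")["mean_prot"].mean().sort_index()
        c = pk.TitrationCurve(noisy, pooled.index.to_numpy(), pooled.to_numpy())
        a, _ = pk.bayesian_bootstrap_sd(c, n_boot=300, seed=11)
        b, _ = pk.bayesian_bootstrap_sd(c, n_boot=300, seed=11)
        assert a == b and a > 0

    def test_matches_high_repetition_oracle(self):
        # two replicates, known spread: 10^4-resample run approximates a
        # 10^5-resample oracle of the same scheme within 10%
        rows = []
        rng = np.random.default_rng(8)
        for rep in range(2):
            for replica, ph in enumerate(LADDER):
                m = float(np.clip(hill_protonation(ph, 6.0) + rng.normal(0, 0.05), 0, 1))
                rows.append(
                    dict(replicate=rep, replica=replica, ph=ph,
                         n_frames=100, n_prot=int(100 * m), mean_prot=m)
                )
        cells = pd.DataFrame(rows)
        pooled = cells.groupby("ph")["mean_prot"].mean().sort_index()
        curve = pk.TitrationCurve(cells, pooled.index.to_numpy(), pooled.to_numpy())
        fast, _ = pk.bayesian_bootstrap_sd(curve, n_boot=1000, seed=1, fix_hill_n=1.0)
        oracle, _ = pk.bayesian_bootstrap_sd(curve, n_boot=10000, seed=2, fix_hill_n=1.0)
        assert fast == pytest.approx(oracle, rel=0.10)


class TestProfileAndSummary:
    def test_flat_truth_recovered_with_deep_window_summary(self, small_frames):
        cfg = pk.ProfileConfig(n_boot=150, seed=2)
        profile = pk.build_profile(small_frames, cfg)
        assert len(profile.estimates) >= 3
        for e in profile.estimates:
            assert e.pka == pytest.approx(6.0, abs=max(3 * e.bootstrap_sd, 0.08))
        ins = pk.pka_ins(profile, cfg.deep_window)
        if ins.defined:
            assert ins.value == pytest.approx(6.0, abs=0.1)

    def test_single_bin_window(self):
        est = pk.PKaEstimate(
            bin=pk.InsertionBin(-5.5, -5.0),
            pka=6.3,
            hill_n=1.0,
            bootstrap_sd=0.05,
            n_frames=500,
            criteria=pk.CriteriaLedger(True, True, True),
        )
        profile = pk.PKaProfile(estimates=(est,))
        assert pk.pka_ins(profile).value == pytest.approx(6.3)

    def test_empty_window_undefined(self):
        est = pk.PKaEstimate(
            bin=pk.InsertionBin(-1.0, -0.5),
            pka=6.1,
            hill_n=1.0,
            bootstrap_sd=0.05,
            n_frames=500,
            criteria=pk.CriteriaLedger(True, True, True),
        )
        res = pk.pka_ins(pk.PKaProfile(estimates=(est,)))
        assert not res.defined and np.isnan(res.value)

    def test_equilibration_discard_drops_leading_time(self, small_frames):
        kept = pk.discard_equilibration(small_frames, 0.3)
        t_max = small_frames["time_ps"].max()
        assert kept["time_ps"].min() >= 0.3 * t_max - 1e-9
        assert len(kept) < len(small_frames)

    def test_time_blocks_partition_each_replicate(self, small_frames):
        blocked = pk.add_time_blocks(small_frames, 6)
        assert set(blocked["block"].unique()) == set(range(6))
        assert len(blocked) == len(small_frames)
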