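"""Shared fixtures: deterministic synthetic datasets and brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest


def brute_force_pairs(a, b, box=None):
    """All-pairs minimum-image distances via explicit Python loops (oracle)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    out = np.empty((len(a), len(b)))
    for i, p in enumerate(a):
        for j, q in enumerate(b):
            s = 0.0
            for k in range(p.shape[0]):
                d = p[k] - q[k]
                if box is not None and k < len(box):
                    d -= box[k] * round(d / box[k])
                s += d * d
            out[i, j] = math.sqrt(s)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def small_frames():
    """A compact pHRE frame set from a flat ground-truth profile (pKa 6.0)."""
    from pkamem import synthetic_data as syn

    profile = syn.GroundTruthProfile.linear((-6.0, 0.0), (6.0, 6.0))
    cfg = syn.SyntheticConfig(n_frames=4000, seed=5, depth_bounds=(-6.0, 0.0))
    return syn.generate_phre_frames(profile, cfg)


def make_criteria_frames(
    cells: dict,
    ph_ladder=(5.0, 5.75, 6.5, 7.25),
) -> pd.DataFrame:
    """Build bin frames with exact per-(replicate, replica/pH) state counts.

    ``cells`` maps (replicate, replica) -> {ph: (n_prot, n_deprot)}.
    """
    rows = []
    t = 0
    for (rep, replica), by_ph in cells.items():
        for ph, (n_prot, n_deprot) in by_ph.items():
            for state, n in ((1, n_prot), (0, n_deprot)):
                for _ in range(n):
                    rows.append(
                        dict(
                            replicate=rep,
                            replica=replica,
                            ph=ph,
                            time_ps=float(t),
                            insertion_A=-2.25,
                            prot_asp=state,
                        )
                    )
                    t += 20
    return pd.DataFrame(rows)
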