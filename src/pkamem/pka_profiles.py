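"""Insertion-binned pKa profiles from constant-pH replica-exchange frames.

Frames carrying (replicate, replica, pH, time, insertion depth, binary
protonation) are sliced into 0.5 Å insertion bins.  Each bin yields a
titration curve — per-(replicate, replica) average protonations versus the
ladder pH — which is fitted with the Hill equation to give the bin's pKa.
Before fitting, three screening criteria guard against under-sampled or
inconsistent bins:

1. every (replicate, pH) cell with data holds at least 10 frames of *each*
   protonation state;
2. the bin's data come from at least three replicates, each contributing at
   least two replicas;
3. the pooled titration curve is monotone: average protonation at a pH may
   not exceed that of the previous (lower) pH by more than 0.05.

Uncertainties are Bayesian-bootstrap standard deviations: replicates are
reweighted with flat Dirichlet draws and the Hill fit repeated; resamples
that fail the screening are discarded and redrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._utils import hill_protonation, substream

__all__ = [
    "InsertionBin",
    "CriteriaLedger",
    "TitrationCurve",
    "PKaEstimate",
    "PKaProfile",
    "PkaInsResult",
    "ProfileConfig",
    "slice_by_insertion",
    "build_titration_curve",
    "check_criteria",
    "fit_pka",
    "bayesian_bootstrap_sd",
    "build_profile",
    "pka_ins",
]

BIN_WIDTH = 0.5


@dataclass(frozen=True, order=True)
class InsertionBin:
    """Half-open insertion slice [lower, upper) in Å, anchored at multiples of the width."""

    lower: float
    upper: float

    def __post_init__(self):
        if not math.isclose(self.upper - self.lower, BIN_WIDTH, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"bin width must be {BIN_WIDTH} Å")

    @classmethod
    def of(cls, insertion: float, width: float = BIN_WIDTH) -> "InsertionBin":
        k = math.floor(insertion / width)
        return cls(lower=round(k * width, 6), upper=round((k + 1) * width, 6))

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def __contains__(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass(frozen=True)
class CriteriaLedger:
    """Pass/fail record of the three screening criteria, with diagnostics."""

    c1_state_counts: bool
    c2_replicate_coverage: bool
    c3_monotonic: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return self.c1_state_counts and self.c2_replicate_coverage and self.c3_monotonic

    def as_dict(self) -> dict:
        return {
            "c1_state_counts": self.c1_state_counts,
            "c2_replicate_coverage": self.c2_replicate_coverage,
            "c3_monotonic": self.c3_monotonic,
        }


@dataclass(frozen=True)
class TitrationCurve:
    """Per-cell average protonations of one bin plus the pooled curve.

    ``cells`` has one row per (replicate, replica, ph) with columns
    ``n_frames``, ``n_prot``, ``mean_prot``; ``ph_values`` /
    ``mean_protonation`` give the frame-pooled curve per ladder pH.
    """

    cells: pd.DataFrame
    ph_values: np.ndarray
    mean_protonation: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean_protonation, dtype=float)
        if m.size and (m.min() < -1e-9 or m.max() > 1 + 1e-9):
            raise ValueError("mean protonation must lie in [0, 1]")

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.mean_protonation) <= 0.05 + 1e-12))


@dataclass(frozen=True)
class PKaEstimate:
    """One bin's Hill fit: pKa, cooperativity, bootstrap sd, criteria ledger."""

    bin: InsertionBin
    pka: float
    hill_n: float
    bootstrap_sd: float
    n_frames: int
    criteria: CriteriaLedger
    converged: bool = True

    def __post_init__(self):
        if np.isfinite(self.bootstrap_sd) and self.bootstrap_sd < 0:
            raise ValueError("bootstrap sd must be >= 0")


@dataclass(frozen=True)
class PkaInsResult:
    """Deep-window summary pKa; ``value`` is NaN when the window is empty."""

    value: float
    status: str
    n_bins: int
    n_frames: int

    @property
    def defined(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class PKaProfile:
    """Ordered criteria-passing bin estimates plus the rejected-bin ledger."""

    estimates: tuple
    rejected: tuple = ()

    def __post_init__(self):
        bins = [e.bin for e in self.estimates]
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("estimates must be strictly ordered by depth")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            rows.append(
                {
                    "bin_low": e.bin.lower,
                    "bin_high": e.bin.upper,
                    "pka": e.pka,
                    "hill_n": e.hill_n,
                    "sd": e.bootstrap_sd,
                    "n_frames": e.n_frames,
                    **e.criteria.as_dict(),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProfileConfig:
    """All thresholds of the profile pipeline, at their standard defaults."""

    bin_width: float = BIN_WIDTH
    min_state_points: int = 10
    min_replicates: int = 3
    min_replicas_per_replicate: int = 2
    monotonic_tol: float = 0.05
    monotonic_remedy: str = "drop_ph"  # or "drop_bin"
    state_count_remedy: str = "drop_ph"  # or "drop_cells" / "drop_bin"
    fix_hill_n: float | None = None
    n_boot: int = 1000
    seed: int = 0
    equilibration_fraction: float = 0.3
    deep_window: tuple[float, float] = (-6.0, -5.0)
    bootstrap_blocks: int = 8

    def __post_init__(self):
        if self.monotonic_remedy not in ("drop_ph", "drop_bin"):
            raise ValueError("monotonic_remedy must be 'drop_ph' or 'drop_bin'")
        if self.state_count_remedy not in ("drop_ph", "drop_cells", "drop_bin"):
            raise ValueError("state_count_remedy must be 'drop_ph', 'drop_cells' or 'drop_bin'")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.bootstrap_blocks < 1:
            raise ValueError("bootstrap_blocks must be >= 1")


def slice_by_insertion(
    frames: pd.DataFrame, bin_width: float = BIN_WIDTH
) -> dict[InsertionBin, pd.DataFrame]:
    """Partition frames into half-open insertion bins anchored at multiples of the width."""
    if frames.empty:
        return {}
    idx = np.floor(frames["insertion_A"].to_numpy(dtype=float) / bin_width).astype(int)
    out = {}
    for k, sub in frames.groupby(idx):
        b = InsertionBin(lower=round(k * bin_width, 6), upper=round((k + 1) * bin_width, 6))
        out[b] = sub
    return dict(sorted(out.items()))


def build_titration_curve(bin_frames: pd.DataFrame, prot_col: str = "prot_asp") -> TitrationCurve:
    """Per-(replicate[, block], replica, pH) average protonations of one bin's frames.

    If the frames carry a ``block`` column (time-block averaging), each
    block contributes its own average-protonation sample.
    """
    keys = ["replicate", "replica", "ph"]
    if "block" in bin_frames.columns:
        keys = ["replicate", "block", "replica", "ph"]
    g = bin_frames.groupby(keys)[prot_col]
    cells = g.agg(n_frames="size", n_prot="sum", mean_prot="mean").reset_index()
    pooled = bin_frames.groupby("ph")[prot_col].mean().sort_index()
    return TitrationCurve(
        cells=cells,
        ph_values=pooled.index.to_numpy(dtype=float),
        mean_protonation=pooled.to_numpy(dtype=float),
    )


def check_criteria(
    bin_frames: pd.DataFrame,
    min_state_points: int = 10,
    min_replicates: int = 3,
    min_replicas_per_replicate: int = 2,
    monotonic_tol: float = 0.05,
    prot_col: str = "prot_asp",
) -> CriteriaLedger:
    """Evaluate the three screening criteria on one bin's frames."""
    diagnostics: dict = {}

    # 1 — every (replicate, pH) cell with data needs >= min points of each state
    cell = bin_frames.groupby(["replicate", "ph"])[prot_col].agg(["size", "sum"])
    n_prot = cell["sum"]
    n_deprot = cell["size"] - cell["sum"]
    bad = cell[(n_prot < min_state_points) | (n_deprot < min_state_points)]
    c1 = len(bad) == 0 and len(cell) > 0
    if len(bad):
        diagnostics["c1_undersized_cells"] = [
            {"replicate": int(r), "ph": float(p), "n_prot": int(np), "n_deprot": int(nd)}
            for (r, p), np, nd in zip(bad.index, n_prot[bad.index], n_deprot[bad.index])
        ]

    # 2 — >= min_replicates replicates, each with >= min_replicas distinct replicas
    per_rep = bin_frames.groupby("replicate")["replica"].nunique()
    enough_reps = len(per_rep) >= min_replicates
    enough_replicas = bool((per_rep >= min_replicas_per_replicate).all()) and len(per_rep) > 0
    c2 = enough_reps and enough_replicas
    diagnostics["c2_replicas_per_replicate"] = {int(k): int(v) for k, v in per_rep.items()}

    # 3 — pooled curve monotone within tolerance (protonation falls with pH)
    curve = build_titration_curve(bin_frames, prot_col=prot_col)
    rises = np.diff(curve.mean_protonation)
    violating = np.where(rises > monotonic_tol)[0] + 1
    c3 = violating.size == 0
    if violating.size:
        diagnostics["c3_violating_ph"] = [float(curve.ph_values[i]) for i in violating]

    return CriteriaLedger(
        c1_state_counts=bool(c1),
        c2_replicate_coverage=bool(c2),
        c3_monotonic=bool(c3),
        diagnostics=diagnostics,
    )


def _hill(ph, pka, n):
    return hill_protonation(ph, pka, n)


def fit_pka(
    curve: TitrationCurve,
    fix_hill_n: float | None = None,
    drop_ph: Sequence[float] = (),
    cell_weights=None,
):
    """Hill fit of a bin's titration curve; returns ``(pka, hill_n, converged)``.

    Fit points are the per-(replicate, replica) average protonations, one
    point per cell, weighted by the cell's frame count (a cell mean's
    variance scales as 1/n, so frame-count weighting is the
    inverse-variance choice; it also makes the fit identical to a pooled
    per-frame fit).  ``cell_weights`` multiplies the frame-count weights
    with per-sample Dirichlet draws during bootstrapping, aligned with the
    retained cells.  ``drop_ph`` removes monotonicity-violating pH values
    from the fit.
    """
    cells = curve.cells
    if drop_ph:
        cells = cells[~cells["ph"].isin(list(drop_ph))]
    if cells["ph"].nunique() < 3:
        raise ValueError("need at least 3 pH points to fit a titration curve")
    ph = cells["ph"].to_numpy(dtype=float)
    y = cells["mean_prot"].to_numpy(dtype=float)
    w = cells["n_frames"].to_numpy(dtype=float)
    if cell_weights is not None:
        cw = np.asarray(cell_weights, dtype=float)
        if cw.shape != ph.shape:
            raise ValueError("cell_weights must align with the retained cells")
        w = w * np.clip(cw, 1e-12, None)
    sigma = 1.0 / np.sqrt(w)
    pka0 = float(np.interp(0.5, y[np.argsort(y)], ph[np.argsort(y)]))
    try:
        if fix_hill_n is None:
            popt, _ = curve_fit(
                _hill, ph, y, p0=(pka0, 1.0), sigma=sigma, method="lm", maxfev=10000
            )
            pka, n = float(popt[0]), float(popt[1])
        else:
            popt, _ = curve_fit(
                lambda x, pka: _hill(x, pka, fix_hill_n),
                ph,
                y,
                p0=(pka0,),
                sigma=sigma,
                method="lm",
                maxfev=10000,
            )
            pka, n = float(popt[0]), float(fix_hill_n)
    except RuntimeError:
        return float("nan"), float("nan"), False
    if n <= 0:
        return pka, n, False
    return pka, n, True


def bayesian_bootstrap_sd(
    curve: TitrationCurve,
    n_boot: int = 1000,
    seed: int = 0,
    fix_hill_n: float | None = None,
    drop_ph: Sequence[float] = (),
    monotonic_tol: float = 0.05,
    max_draw_factor: int = 5,
) -> tuple[float, int]:
    """Bayesian-bootstrap sd of a bin's pKa.

    Each resample draws flat Dirichlet weights over the average-protonation
    samples (one per retained (replicate, replica, pH) cell), refits the
    Hill curve with those weights, and records the pKa.  Resamples whose
    weighted pooled curve violates the monotonicity tolerance, or whose fit
    fails, are discarded and redrawn (the discard count is returned).  All
    resamples failing leaves the sd undefined (NaN).
    """
    cells = curve.cells[~curve.cells["ph"].isin(list(drop_ph))] if drop_ph else curve.cells
    if cells["replicate"].nunique() < 2:
        raise ValueError("need at least two replicates to bootstrap")
    rng = substream(seed, "bayesian-bootstrap")
    n_cells = len(cells)
    ph_codes, ph_unique = pd.factorize(cells["ph"], sort=True)
    frame_w = cells["n_frames"].to_numpy(dtype=float)
    means = cells["mean_prot"].to_numpy(dtype=float)
    pkas = []
    discarded = 0
    attempts = 0
    while len(pkas) < n_boot and attempts < max_draw_factor * n_boot:
        attempts += 1
        w = rng.dirichlet(np.ones(n_cells)) * n_cells
        fw = w * frame_w
        pooled = np.bincount(ph_codes, weights=fw * means) / np.bincount(
            ph_codes, weights=fw
        )
        if np.any(np.diff(pooled) > monotonic_tol):
            discarded += 1
            continue
        pka, _, ok = fit_pka(curve, fix_hill_n=fix_hill_n, drop_ph=drop_ph, cell_weights=w)
        if not ok or not np.isfinite(pka):
            discarded += 1
            continue
        pkas.append(pka)
    if not pkas:
        return float("nan"), discarded
    return float(np.std(pkas, ddof=0)), discarded


def discard_equilibration(frames: pd.DataFrame, fraction: float = 0.3) -> pd.DataFrame:
    """Drop the leading ``fraction`` of each replicate's time range (equilibration)."""
    if fraction <= 0:
        return frames
    t_max = frames.groupby("replicate")["time_ps"].transform("max")
    return frames[frames["time_ps"] >= fraction * t_max]


def drop_undersized_cells(
    bin_frames: pd.DataFrame,
    min_state_points: int = 10,
    prot_col: str = "prot_asp",
    per_ph: bool = True,
) -> pd.DataFrame:
    """Remove data failing the minimum-state-count screen from a bin.

    A cell whose minority protonation state is barely sampled yields an
    unreliable average protonation.  With ``per_ph`` (the default) the whole
    pH level is excluded from the bin as soon as any replicate's cell at
    that pH is undersized — dropping the level wholesale avoids selecting
    individual cells on their own outcome, which would bias the retained
    means toward the minority state.  ``per_ph=False`` drops only the
    offending cells.
    """
    cell = bin_frames.groupby(["replicate", "ph"])[prot_col].agg(["size", "sum"])
    ok = cell[(cell["sum"] >= min_state_points)
              & (cell["size"] - cell["sum"] >= min_state_points)]
    if per_ph:
        bad = cell.index[~cell.index.isin(ok.index)]
        bad_ph = set(bad.get_level_values("ph"))
        return bin_frames[~bin_frames["ph"].isin(bad_ph)]
    key = pd.MultiIndex.from_frame(bin_frames[["replicate", "ph"]])
    return bin_frames[key.isin(ok.index)]


def add_time_blocks(frames: pd.DataFrame, n_blocks: int) -> pd.DataFrame:
    """Label frames with equal-time blocks per replicate (for block averaging).

    Block averages stand in for approximately independent samples when
    forming bootstrap uncertainties — the standard practice for correlated
    simulation time series; more, shorter blocks also condition the
    dispersion estimate better when per-replicate bin occupancy is heavy-
    tailed.
    """
    if n_blocks <= 1:
        return frames
    out = frames.copy()
    t = out["time_ps"].to_numpy(dtype=float)
    lo = out.groupby("replicate")["time_ps"].transform("min").to_numpy()
    hi = out.groupby("replicate")["time_ps"].transform("max").to_numpy()
    span = np.where(hi > lo, hi - lo, 1.0)
    out["block"] = np.minimum((n_blocks * (t - lo) / span).astype(int), n_blocks - 1)
    return out


def build_profile(frames: pd.DataFrame, config: ProfileConfig = ProfileConfig()) -> PKaProfile:
    """Slice frames, screen every bin, fit the survivors, attach bootstrap errors."""
    kept = discard_equilibration(frames, config.equilibration_fraction)
    kept = add_time_blocks(kept, config.bootstrap_blocks)
    estimates, rejected = [], []
    for b, sub in slice_by_insertion(kept, config.bin_width).items():
        ledger = check_criteria(
            sub,
            min_state_points=config.min_state_points,
            min_replicates=config.min_replicates,
            min_replicas_per_replicate=config.min_replicas_per_replicate,
            monotonic_tol=config.monotonic_tol,
        )
        if not ledger.c1_state_counts:
            if config.state_count_remedy == "drop_bin":
                rejected.append((b, ledger))
                continue
            sub = drop_undersized_cells(
                sub,
                config.min_state_points,
                per_ph=config.state_count_remedy == "drop_ph",
            )
            if sub.empty:
                rejected.append((b, ledger))
                continue
            # re-screen the retained data: criterion 1 holds by construction,
            # but replicate coverage and monotonicity may have changed
            rescreened = check_criteria(
                sub,
                min_state_points=config.min_state_points,
                min_replicates=config.min_replicates,
                min_replicas_per_replicate=config.min_replicas_per_replicate,
                monotonic_tol=config.monotonic_tol,
            )
            ledger = replace(
                rescreened,
                diagnostics={
                    **ledger.diagnostics,
                    **rescreened.diagnostics,
                    "c1_cells_dropped": True,
                },
            )
        drop_ph: tuple = ()
        effective_c3 = ledger.c3_monotonic
        if not ledger.c3_monotonic and config.monotonic_remedy == "drop_ph":
            drop_ph = tuple(ledger.diagnostics.get("c3_violating_ph", ()))
            effective_c3 = True
        if not (ledger.c1_state_counts and ledger.c2_replicate_coverage and effective_c3):
            rejected.append((b, ledger))
            continue
        curve = build_titration_curve(sub)
        if curve.cells["ph"].nunique() - len(drop_ph) < 3:
            rejected.append((b, ledger))
            continue
        pka, n, ok = fit_pka(curve, fix_hill_n=config.fix_hill_n, drop_ph=drop_ph)
        if not ok:
            rejected.append((b, ledger))
            continue
        sd, _ = bayesian_bootstrap_sd(
            curve,
            n_boot=config.n_boot,
            seed=config.seed,
            fix_hill_n=config.fix_hill_n,
            drop_ph=drop_ph,
            monotonic_tol=config.monotonic_tol,
        )
        if not np.isfinite(sd):
            rejected.append((b, ledger))
            continue
        estimates.append(
            PKaEstimate(
                bin=b,
                pka=pka,
                hill_n=n,
                bootstrap_sd=sd,
                n_frames=len(sub),
                criteria=replace(ledger, c3_monotonic=effective_c3),
            )
        )
    return PKaProfile(estimates=tuple(estimates), rejected=tuple(rejected))


def pka_ins(
    profile: PKaProfile, deep_window: tuple[float, float] = (-6.0, -5.0)
) -> PkaInsResult:
    """Count-weighted mean pKa over bins lying fully inside the deep window."""
    lo, hi = deep_window
    inside = [e for e in profile.estimates if e.bin.lower >= lo and e.bin.upper <= hi]
    if not inside:
        return PkaInsResult(value=float("nan"), status="undefined: no bins in window",
                            n_bins=0, n_frames=0)
    w = np.array([e.n_frames for e in inside], dtype=float)
    v = np.array([e.pka for e in inside], dtype=float)
    return PkaInsResult(
        value=float(np.average(v, weights=w)),
        status="ok",
        n_bins=len(inside),
        n_frames=int(w.sum()),
    )
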