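"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data a constant-pH replica-exchange (pHRE)
simulation of a membrane-inserting peptide would produce, plus the
experimental-style titration and stopped-flow tables:

* a two-leaflet phosphate lattice with an optional parametric deformation,
* per-frame records (replicate, replica, pH, time, insertion depth, binary
  protonation) sampled from a depth-dependent ground-truth pKa profile,
* depth-dependent interaction-shell count channels,
* Hill-shaped pH-response curves and sums-of-exponentials kinetic traces.

Every generator is a pure function of its parameters and a seed, drawing
from a named substream per channel so generators never perturb each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import hill_protonation, substream

__all__ = [
    "GroundTruthProfile",
    "SyntheticConfig",
    "GaussianDimple",
    "Bilayer",
    "generate_bilayer",
    "generate_phre_frames",
    "generate_contact_profiles",
    "generate_titration_experiment",
    "generate_kinetic_trace",
]

#: pH ladder used throughout: 5.00 to 7.25 in 0.75 steps (four replicas).
DEFAULT_PH_LADDER = (5.00, 5.75, 6.50, 7.25)


@dataclass(frozen=True)
class GroundTruthProfile:
    """Depth-dependent true pKa of the tracked titrable residue.

    ``bin_centers`` are signed insertion depths in Å (negative = below the
    outer phosphate surface).  Values between centers are linearly
    interpolated; outside the covered range the terminal value is held.
    """

    bin_centers: np.ndarray
    pka_values: np.ndarray
    hill_n: np.ndarray | float = 1.0

    def __post_init__(self):
        centers = np.asarray(self.bin_centers, dtype=float)
        pkas = np.asarray(self.pka_values, dtype=float)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("bin_centers must be a non-empty 1-D array")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if pkas.shape != centers.shape or not np.all(np.isfinite(pkas)):
            raise ValueError("pka_values must be finite and match bin_centers")
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "pka_values", pkas)
        n = np.asarray(self.hill_n, dtype=float)
        if n.ndim == 0:
            n = np.full_like(centers, float(n))
        if n.shape != centers.shape or np.any(n <= 0):
            raise ValueError("hill_n must be positive, scalar or per-center")
        object.__setattr__(self, "hill_n", n)

    def pka_at(self, depth) -> np.ndarray:
        return np.interp(depth, self.bin_centers, self.pka_values)

    def hill_at(self, depth) -> np.ndarray:
        return np.interp(depth, self.bin_centers, self.hill_n)

    @classmethod
    def linear(cls, depth_range=(-6.0, 0.0), pka_range=(7.0, 6.0), hill_n=1.0):
        """Straight-line profile, e.g. a desolvation-like +1 shift over 6 Å."""
        lo, hi = depth_range
        return cls(np.array([lo, hi]), np.array(list(pka_range)), hill_n)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic pHRE run.

    Defaults mirror the simulated setup the pipeline targets: five
    replicates, a four-replica pH ladder from 5.00 to 7.25 (0.75 step), and
    100 ns per replica sampled every 20 ps (5000 frames).
    """

    n_replicates: int = 5
    ph_ladder: Sequence[float] = DEFAULT_PH_LADDER
    n_frames: int = 5000
    seed: int = 0
    frame_dt_ps: float = 20.0
    depth_bounds: tuple[float, float] = (-8.0, 2.0)
    depth_step_sd: float = 0.5

    def __post_init__(self):
        ladder = tuple(float(p) for p in self.ph_ladder)
        if len(ladder) == 0:
            raise ValueError("ph_ladder must not be empty")
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ph_ladder must be sorted strictly ascending")
        object.__setattr__(self, "ph_ladder", ladder)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if self.depth_step_sd < 0:
            raise ValueError("depth_step_sd must be >= 0")
        lo, hi = self.depth_bounds
        if not lo < hi:
            raise ValueError("depth_bounds must be an increasing pair")


@dataclass(frozen=True)
class GaussianDimple:
    """Radial Gaussian perturbation of one leaflet's z coordinates (Å).

    ``amplitude`` is added to z at the center and decays with lateral
    distance; a negative amplitude on the upper leaflet is a dimple toward
    the bilayer midplane.
    """

    amplitude: float
    width: float
    center: tuple[float, float] = (0.0, 0.0)
    leaflet: str = "upper"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.leaflet not in ("upper", "lower", "both"):
            raise ValueError("leaflet must be 'upper', 'lower' or 'both'")

    def __call__(self, x, y):
        dx = np.asarray(x, dtype=float) - self.center[0]
        dy = np.asarray(y, dtype=float) - self.center[1]
        return self.amplitude * np.exp(-(dx**2 + dy**2) / (2.0 * self.width**2))


@dataclass(frozen=True)
class Bilayer:
    """Phosphate point sets of the two leaflets plus the periodic xy box."""

    upper: np.ndarray
    lower: np.ndarray
    box_xy: np.ndarray

    @property
    def all_phosphates(self) -> np.ndarray:
        return np.vstack([self.upper, self.lower])

    def to_gro(self, path, name="synthetic bilayer"):
        """Write a minimal fixed-width GRO-dialect coordinate file (nm)."""
        coords = self.all_phosphates / 10.0  # Å -> nm
        box = np.array([self.box_xy[0], self.box_xy[1], 100.0]) / 10.0
        with open(path, "w") as fh:
            fh.write(f"{name}\n{len(coords):5d}\n")
            for i, (x, y, z) in enumerate(coords, start=1):
                fh.write(
                    f"{i % 100000:5d}{'POPC':<5s}{'P':>5s}{i % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def generate_bilayer(
    n_lipids_per_leaflet: int,
    half_thickness: float,
    deformation_field: Callable | None = None,
    seed: int = 0,
    area_per_lipid: float = 64.0,
    atoms_per_lipid: int = 1,
    headgroup_spread: float = 1.0,
    z_noise: float = 0.3,
) -> Bilayer:
    """Two flat phosphate leaflets at ±half_thickness with optional deformation.

    Lipids sit on a jittered square lattice sized from ``area_per_lipid``
    (64 Å², a fluid-phase phosphatidylcholine value); each lipid contributes
    ``atoms_per_lipid`` phosphate-group atoms scattered within
    ``headgroup_spread`` Å of its site.  ``deformation_field(x, y)`` is added
    to z on the leaflet(s) it declares (attribute ``leaflet``, default upper).
    """
    if n_lipids_per_leaflet < 16:
        raise ValueError("n_lipids_per_leaflet must be >= 16")
    if half_thickness <= 0:
        raise ValueError("half_thickness must be positive")
    if atoms_per_lipid < 1:
        raise ValueError("atoms_per_lipid must be >= 1")
    rng = substream(seed, "bilayer")
    side = int(np.ceil(np.sqrt(n_lipids_per_leaflet)))
    spacing = float(np.sqrt(area_per_lipid))
    box = np.array([side * spacing, side * spacing])

    leaflets = []
    for sign, tag in ((+1.0, "upper"), (-1.0, "lower")):
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        sites = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[
            :n_lipids_per_leaflet
        ]
        sites = (sites + 0.5) * spacing
        sites += rng.normal(scale=0.15 * spacing, size=sites.shape)
        sites %= box
        atoms = np.repeat(sites, atoms_per_lipid, axis=0)
        if atoms_per_lipid > 1:
            atoms += rng.normal(scale=headgroup_spread, size=atoms.shape)
            atoms %= box
        z = np.full(len(atoms), sign * half_thickness)
        z += rng.normal(scale=z_noise, size=z.shape)
        if deformation_field is not None:
            applies_to = getattr(deformation_field, "leaflet", "upper")
            if applies_to in (tag, "both"):
                z = z + deformation_field(atoms[:, 0], atoms[:, 1])
        leaflets.append(np.column_stack([atoms, z]))
    return Bilayer(upper=leaflets[0], lower=leaflets[1], box_xy=box)


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    span = hi - lo
    v = np.mod(values - lo, 2.0 * span)
    return lo + np.where(v > span, 2.0 * span - v, v)


def generate_phre_frames(
    profile: GroundTruthProfile, cfg: SyntheticConfig
) -> pd.DataFrame:
    """Per-frame pHRE observations sampled from a ground-truth pKa profile.

    Each (replicate, replica) pair follows an independent reflected Gaussian
    random walk in insertion depth; the binary protonation state at depth z
    and replica pH is drawn with P(protonated) = 1/(1 + 10^{n(z)·(pH −
    pKa(z))}).  Columns: replicate, replica, ph, time_ps, insertion_A,
    prot_asp.
    """
    lo, hi = cfg.depth_bounds
    frames = []
    for rep in range(cfg.n_replicates):
        for replica, ph in enumerate(cfg.ph_ladder):
            rng = substream(cfg.seed, f"phre/rep{rep}/replica{replica}")
            if cfg.n_frames == 0:
                depths = np.empty(0)
            else:
                start = rng.uniform(lo, hi)
                steps = rng.normal(scale=cfg.depth_step_sd, size=cfg.n_frames)
                steps[0] = 0.0
                depths = _reflect(start + np.cumsum(steps), lo, hi)
            p_prot = hill_protonation(ph, profile.pka_at(depths), profile.hill_at(depths))
            prot = (rng.random(cfg.n_frames) < p_prot).astype(np.int8)
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": np.full(cfg.n_frames, rep, dtype=np.int32),
                        "replica": np.full(cfg.n_frames, replica, dtype=np.int32),
                        "ph": np.full(cfg.n_frames, ph),
                        "time_ps": np.arange(cfg.n_frames) * cfg.frame_dt_ps,
                        "insertion_A": depths,
                        "prot_asp": prot,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_contact_profiles(
    depths,
    mean_functions: Mapping[str, Callable],
    dispersion: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame interaction-shell counts for the named partner channels.

    ``mean_functions`` maps a channel name (e.g. ``n_phos``, ``n_chol``,
    ``n_hbond``, ``arg_contact``) to a depth -> mean-count function.  With
    ``dispersion > 0`` counts are Poisson-distributed around the mean;
    ``dispersion == 0`` gives deterministic rounded means.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    depths = np.asarray(depths, dtype=float)
    out = {}
    for name, fn in mean_functions.items():
        means = np.asarray(fn(depths), dtype=float)
        if means.shape != depths.shape or not np.all(np.isfinite(means)):
            raise ValueError(f"mean function for {name!r} undefined at a sampled depth")
        if np.any(means < 0):
            raise ValueError(f"mean function for {name!r} produced negative means")
        if dispersion == 0:
            counts = np.rint(means).astype(np.int64)
        else:
            rng = substream(seed, f"contacts/{name}")
            counts = rng.poisson(means)
        out[name] = counts
    return pd.DataFrame(out)


def generate_titration_experiment(
    pk: float,
    n: float,
    baseline: float,
    span: float,
    noise_sd: float,
    ph_grid,
    seed: int = 0,
) -> pd.DataFrame:
    """pH-response table: baseline + span·Hill(pH; pK, n) + Gaussian noise.

    The Hill term is the protonated fraction, so the acidic plateau sits at
    ``baseline + span``.
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise ValueError("ph_grid must not be empty")
    if span == 0:
        raise ValueError("span must be non-zero")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    response = baseline + span * hill_protonation(ph, pk, n)
    if noise_sd > 0:
        response = response + substream(seed, "titration").normal(scale=noise_sd, size=ph.shape)
    return pd.DataFrame({"ph": ph, "response": response})


def generate_kinetic_trace(
    amplitudes,
    taus,
    noise_sd: float,
    t_grid,
    seed: int = 0,
    offset: float = 0.0,
) -> pd.DataFrame:
    """Time-intensity table: offset + Σ aᵢ·exp(−t/τᵢ) + Gaussian noise."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if amplitudes.size != taus.size or taus.size < 1:
        raise ValueError("amplitudes and taus must have equal length >= 1")
    if np.any(taus <= 0):
        raise ValueError("all characteristic times must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(t_grid, dtype=float)
    intensity = offset + np.sum(
        amplitudes[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0
    )
    if noise_sd > 0:
        intensity = intensity + substream(seed, "kinetics").normal(scale=noise_sd, size=t.shape)
    return pd.DataFrame({"time": t, "intensity": intensity})
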