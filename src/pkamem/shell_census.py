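"""First-interaction-shell censuses around the key carboxylate.

Counts the partner groups (lipid phosphates, cholines, water hydrogen
bonds, the arginine guanidinium) found within a fixed radial cutoff of the
tracked aspartate side chain.  The default shell cutoff is 5.2 Å, taken
from radial-distribution-function minima for phosphate/choline/water around
a membrane-inserted carboxylate.  Counting is group-level: a partner group
counts once no matter how many of its atoms enter the shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import pairwise_distances

__all__ = [
    "ShellCounts",
    "count_in_shell",
    "min_sidechain_distance",
    "salt_bridge_occupancy",
    "count_water_hbonds",
]

#: First-interaction-shell cutoff (Å), from RDF minima.
SHELL_CUTOFF = 5.2
#: Conventional carboxylate–guanidinium salt-bridge criterion (Å, heavy atoms).
SALT_BRIDGE_CUTOFF = 4.0


@dataclass(frozen=True)
class ShellCounts:
    """Shell census of one frame."""

    n_phosphate: int
    n_choline: int
    n_water_hbond: int
    arg_in_shell: bool
    frame_time: float = float("nan")

    def __post_init__(self):
        if min(self.n_phosphate, self.n_choline, self.n_water_hbond) < 0:
            raise ValueError("shell counts must be non-negative")


def count_in_shell(
    center_coords,
    partner_coords,
    partner_group_ids=None,
    box=None,
    cutoff: float = SHELL_CUTOFF,
) -> int:
    """Number of partner *groups* with any atom within ``cutoff`` of any center atom.

    ``partner_group_ids`` assigns each partner atom to a group (e.g. one id
    per lipid headgroup); omitted, every atom is its own group.  Distances
    use the minimum-image convention when ``box`` is given.
    """
    centers = np.atleast_2d(np.asarray(center_coords, dtype=float))
    if centers.size == 0:
        raise ValueError("center selection is empty")
    partners = np.atleast_2d(np.asarray(partner_coords, dtype=float))
    if partners.size == 0:
        return 0
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if partner_group_ids is None:
        group_ids = np.arange(len(partners))
    else:
        group_ids = np.asarray(partner_group_ids)
        if group_ids.shape != (len(partners),):
            raise ValueError("partner_group_ids must label every partner atom")
    d = pairwise_distances(centers, partners, box=box)
    atom_in = np.any(d <= cutoff, axis=0)
    return int(np.unique(group_ids[atom_in]).size)


def min_sidechain_distance(asp_coords, arg_coords, box=None) -> float:
    """Minimum atom-pair distance between two side-chain selections (Å)."""
    a = np.atleast_2d(np.asarray(asp_coords, dtype=float))
    b = np.atleast_2d(np.asarray(arg_coords, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both side-chain selections must be non-empty")
    return float(pairwise_distances(a, b, box=box).min())


def salt_bridge_occupancy(min_distances, bridge_cutoff: float = SALT_BRIDGE_CUTOFF) -> float:
    """Fraction of frames whose minimum side-chain distance is within the cutoff."""
    d = np.asarray(min_distances, dtype=float)
    if d.size == 0:
        raise ValueError("distance series is empty")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.count_nonzero(d <= bridge_cutoff) / d.size)


def count_water_hbonds(
    acceptor_coords,
    water_oxygens,
    water_hydrogens,
    box=None,
    d_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> int:
    """Water molecules donating a hydrogen bond to the carboxylate oxygens.

    Geometric criterion: donor(O_w)–acceptor distance ≤ ``d_cutoff`` and the
    O_w–H···acceptor angle within ``angle_cutoff`` degrees of linear (i.e.
    ≥ 180° − cutoff at the hydrogen).  Each water counts at most once.
    """
    acceptors = np.atleast_2d(np.asarray(acceptor_coords, dtype=float))
    if acceptors.size == 0:
        raise ValueError("acceptor selection is empty")
    ow = np.atleast_2d(np.asarray(water_oxygens, dtype=float))
    if ow.size == 0:
        return 0
    hw = np.asarray(water_hydrogens, dtype=float)
    if hw.ndim != 3 or hw.shape[0] != ow.shape[0] or hw.shape[2] != 3:
        raise ValueError(
            "water_hydrogens must have shape (n_waters, n_H, 3) matching water_oxygens"
        )
    from ._utils import minimum_image

    d_oa = pairwise_distances(ow, acceptors, box=box)  # (n_w, n_acc)
    min_angle = np.radians(180.0 - angle_cutoff)
    bonded = np.zeros(len(ow), dtype=bool)
    for w in range(len(ow)):
        close = np.where(d_oa[w] <= d_cutoff)[0]
        if close.size == 0:
            continue
        for h in range(hw.shape[1]):
            v_o = minimum_image(ow[w] - hw[w, h], box)
            for a in close:
                v_a = minimum_image(acceptors[a] - hw[w, h], box)
                no, na = np.linalg.norm(v_o), np.linalg.norm(v_a)
                if no == 0 or na == 0:
                    raise ValueError("degenerate water geometry (coincident atoms)")
                ang = np.arccos(np.clip(np.dot(v_o, v_a) / (no * na), -1.0, 1.0))
                if ang >= min_angle:
                    bonded[w] = True
                    break
            if bonded[w]:
                break
    return int(np.count_nonzero(bonded))
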