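"""Shared numerical helpers: seeded substreams and minimum-image distances."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "minimum_image", "pairwise_distances", "hill_protonation"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent, named random stream derived from ``seed``.

    Each channel of the synthetic generators draws from its own substream so
    that adding a channel never perturbs the draws of another.  The stream is
    a pure function of ``(seed, name)``.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement vectors.

    ``box`` holds the periodic lengths along each axis (entries may be fewer
    than the vector dimension, in which case only the leading axes wrap; this
    covers xy-periodic membrane systems).  ``box=None`` means no periodicity.
    """
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("periodic box lengths must be positive")
    out = delta.copy()
    k = box.shape[-1]
    out[..., :k] -= box * np.round(out[..., :k] / box)
    return out


def pairwise_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    """All-pairs Euclidean distances between two coordinate sets (minimum image)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    delta = minimum_image(a[:, None, :] - b[None, :, :], box)
    return np.sqrt(np.sum(delta**2, axis=-1))


def hill_protonation(ph, pka, n=1.0):
    """Protonated fraction of a titrable site: ``1 / (1 + 10^{n (pH - pKa)})``.

    The Henderson–Hasselbalch logistic generalised with a cooperativity
    exponent n; at pH = pKa the fraction is 1/2 for any n.
    """
    return 1.0 / (1.0 + 10.0 ** (np.asarray(n, dtype=float) * (np.asarray(ph, dtype=float) - pka)))
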