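"""Scalp channel layouts on the unit sphere.

High-density EEG nets are approximated by a spherical (Fibonacci) spiral over
the upper part of the head; the channels nearest the canonical Fz and Cz
positions are renamed to those labels so that anchor-based electrode subsets
("17 frontal channels around Fz", "13 centroparietal channels around Cz")
can be formed on any layout size.

Head coordinate convention: x to the right ear, y to the nasion (anterior),
z to the vertex; all positions unit-norm.
"""

from __future__ import annotations

import numpy as np

#: canonical anchor directions (unit vectors)
CZ_DIR = np.array([0.0, 0.0, 1.0])
FZ_DIR = np.array([0.0, 0.719, 0.695])
OZ_DIR = np.array([0.0, -0.719, 0.695])

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


def spiral_layout(n_channels: int = 128, z_min: float = -0.05):
    """Fibonacci-spiral layout over the head surface.

    Parameters
    ----------
    n_channels
        Number of electrodes.
    z_min
        Lowest z-coordinate covered (slightly below the equator mimics the
        cheek/neck rows of high-density nets).

    Returns
    -------
    names : list of str
    positions : (n_channels, 3) ndarray of unit vectors
    """
    if n_channels < 3:
        raise ValueError("need at least 3 channels for a scalp layout")
    k = np.arange(n_channels)
    z = z_min + (1.0 - z_min) * (k + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = _GOLDEN * k
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)

    names = [f"E{i + 1:03d}" for i in range(n_channels)]
    for label, direction in (("Fz", FZ_DIR), ("Cz", CZ_DIR)):
        idx = int(np.argmax(pos @ direction))
        names[idx] = label
    return names, pos


def channel_index(names, label: str) -> int:
    try:
        return list(names).index(label)
    except ValueError as err:
        raise KeyError(f"channel {label!r} not in layout") from err


def nearest_channels(names, positions, anchor: str, k: int) -> list[str]:
    """The ``k`` channel names nearest an anchor channel (anchor included)."""
    positions = np.asarray(positions)
    ai = channel_index(names, anchor)
    d = np.linalg.norm(positions - positions[ai], axis=1)
    order = np.argsort(d, kind="stable")[:k]
    return [list(names)[i] for i in order]


def channel_adjacency(positions, threshold: float = 0.45) -> np.ndarray:
    """Boolean adjacency matrix: channels closer than ``threshold`` (chord
    distance on the unit sphere) are neighbors. Diagonal is False."""
    positions = np.asarray(positions)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adj = d < threshold
    np.fill_diagonal(adj, False)
    return adj


def gaussian_topography(positions, center_dir, sigma: float = 0.7) -> np.ndarray:
    """Smooth scalp map peaking at ``center_dir``, normalized to max 1."""
    positions = np.asarray(positions)
    c = np.asarray(center_dir, float)
    c = c / np.linalg.norm(c)
    d = np.linalg.norm(positions - c, axis=1)
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    return w / w.max()
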