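"""Optode montage: source/detector geometry and channel definitions.

A channel is a (source, detector) pair measured at both wavelengths.
Channels are classified as ``long`` (cortical) or ``short``
(extracerebral nuisance) by their source-detector separation; the
default cut is 1.5 cm, well between the typical ~3.5 cm long and
~0.8 cm short separations of frontal montages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

SHORT_SEPARATION_CUT_CM = 1.5


@dataclass
class Montage:
    """Geometry of an optode layout.

    Parameters
    ----------
    source_positions, detector_positions
        ``(n, 3)`` arrays of 3-D coordinates in cm.
    channels
        List of ``(source_index, detector_index)`` pairs (0-based).
    short_cut_cm
        Separation below which a channel is classified as short.
    """

    source_positions: np.ndarray
    detector_positions: np.ndarray
    channels: list[tuple[int, int]]
    short_cut_cm: float = SHORT_SEPARATION_CUT_CM
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        self.detector_positions = np.asarray(self.detector_positions, dtype=float)
        for s, d in self.channels:
            if not (0 <= s < len(self.source_positions)):
                raise ConfigurationError(f"channel references unknown source {s}")
            if not (0 <= d < len(self.detector_positions)):
                raise ConfigurationError(f"channel references unknown detector {d}")
        if not self.channel_names:
            self.channel_names = [f"S{s + 1}_D{d + 1}" for s, d in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def separations(self) -> np.ndarray:
        """Source-detector distance per channel, cm."""
        src = self.source_positions[[s for s, _ in self.channels]]
        det = self.detector_positions[[d for _, d in self.channels]]
        return np.linalg.norm(src - det, axis=1)

    @property
    def roles(self) -> list[str]:
        """``"long"`` or ``"short"`` per channel, from the separation cut."""
        return ["short" if sep < self.short_cut_cm else "long" for sep in self.separations]

    @property
    def midpoints(self) -> np.ndarray:
        """Channel midpoint positions (n_channels, 3), cm."""
        src = self.source_positions[[s for s, _ in self.channels]]
        det = self.detector_positions[[d for _, d in self.channels]]
        return 0.5 * (src + det)

    def long_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "long"], dtype=int)

    def short_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "short"], dtype=int)


def frontal_montage(
    n_long: int = 44,
    n_short: int = 8,
    long_separation: float = 3.5,
    short_separation: float = 0.76,
    seed: int | None = None,
) -> Montage:
    """Build a synthetic frontal montage with the requested channel counts.

    Optodes are laid out on a sphere of radius 9.2 cm (approximate adult
    head) over the frontal cortex in an alternating source/detector grid;
    long channels link neighbouring optodes at roughly ``long_separation``
    and each short channel places a dedicated detector next to a source.
    Coordinates are jittered slightly (seeded) so separations spread
    around their mean, as in a real cap.
    """
    rng = np.random.default_rng(seed)
    radius = 9.2
    # grid of optode sites on the frontal part of the sphere
    n_sites = n_long + 8  # enough sites for the requested channels
    n_cols = int(np.ceil(np.sqrt(n_sites * 1.6)))
    n_rows = int(np.ceil(n_sites / n_cols)) + 1
    # common angular step so that grid neighbours sit ~long_separation apart;
    # azimuth spacing is widened by 1/cos(elevation) to keep arc lengths equal
    theta = long_separation / radius

    sites = []
    for i in range(n_rows):
        e0 = 0.08 + i * theta
        for j in range(n_cols):
            a = (j - (n_cols - 1) / 2) * theta / np.cos(e0) + rng.normal(0, 0.008)
            e = e0 + rng.normal(0, 0.008)
            sites.append(
                radius
                * np.array([np.sin(a) * np.cos(e), np.cos(a) * np.cos(e), np.sin(e)])
            )
    sites = np.array(sites)

    # alternate source/detector in a checkerboard over the grid
    src_pos, det_pos = [], []
    site_kind, site_ref = [], []
    for i in range(n_rows):
        for j in range(n_cols):
            k = i * n_cols + j
            if (i + j) % 2 == 0:
                site_kind.append("S")
                site_ref.append(len(src_pos))
                src_pos.append(sites[k])
            else:
                site_kind.append("D")
                site_ref.append(len(det_pos))
                det_pos.append(sites[k])

    # long channels: neighbouring source-detector grid pairs, keeping the
    # n_long pairs whose separation is closest to the requested one (the
    # spherical grid stretches some diagonal links at the cap edges)
    candidates: list[tuple[float, tuple[int, int]]] = []
    for i in range(n_rows):
        for j in range(n_cols):
            k = i * n_cols + j
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii >= n_rows or jj >= n_cols:
                    continue
                k2 = ii * n_cols + jj
                if site_kind[k] == site_kind[k2]:
                    continue
                pair = (site_ref[k], site_ref[k2]) if site_kind[k] == "S" else (
                    site_ref[k2], site_ref[k]
                )
                dist = float(np.linalg.norm(sites[k] - sites[k2]))
                candidates.append((abs(dist - long_separation), pair))
    if len(candidates) < n_long:
        raise ConfigurationError(
            f"montage grid yields only {len(candidates)} long channels, need {n_long}"
        )
    # prefer a realistic spread of separations: accept anything within
    # ~0.6 cm of the target (matching reported montage ranges), fall back
    # to closest-first for the remainder
    candidates.sort(key=lambda c: c[0])
    near = [pair for off, pair in candidates if off <= 0.6]
    rest = [pair for off, pair in candidates if off > 0.6]
    rng.shuffle(near)
    pool = near + rest
    channels = pool[:n_long]

    # short channels: a dedicated detector placed short_separation from a source
    src_pos = list(src_pos)
    used_sources = sorted({s for s, _ in channels})
    for k in range(n_short):
        s = used_sources[k % len(used_sources)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        jitter = rng.normal(0, 0.02)
        det_pos.append(np.array(src_pos[s]) + (short_separation + jitter) * direction)
        channels.append((s, len(det_pos) - 1))

    return Montage(np.array(src_pos), np.array(det_pos), channels)
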