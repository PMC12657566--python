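"""Recording containers for optical and hemodynamic time series.

``OpticalRecording`` carries per-channel, per-wavelength series through
the preprocessing chain; its ``stage`` tag tracks how far along the
chain the data are, so stages cannot be applied out of order.
``HemoRecording`` holds the HbO/HbR concentration-change series (µM)
produced by the modified Beer-Lambert conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, StateError
from .montage import Montage

#: Preprocessing stages in mandatory chain order. ``intensity`` is raw
#: input; every optical-density stage may feed any *later* stage (stages
#: can be skipped deliberately, e.g. in unit tests), but feeding a stage
#: its own or a later stage's output raises :class:`StateError`.
STAGES = (
    "intensity",
    "od",
    "od_tddr",
    "od_ssr",
    "od_interp",
    "hemo",
    "hemo_enhanced",
    "hemo_filtered",
)

Annotation = tuple[float, float, str]  # onset s, duration s, label


def check_stage(current: str, allowed: tuple[str, ...], op: str) -> None:
    if current not in allowed:
        raise StateError(
            f"{op} expects input at stage {allowed}, got {current!r}; "
            "the preprocessing chain must be applied in order"
        )


@dataclass
class OpticalRecording:
    """Time x channel x wavelength optical data with montage metadata.

    ``intensities`` are strictly positive raw counts at stage
    ``"intensity"``; after conversion the same array holds optical
    density (unitless, mean ~0 per channel).
    """

    intensities: np.ndarray  # (n_times, n_channels, n_wavelengths)
    sampling_rate: float
    montage: Montage
    wavelengths: tuple[float, float] = (760.0, 850.0)
    annotations: list[Annotation] = field(default_factory=list)
    stage: str = "intensity"
    bad_channels: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise DataError("intensities must be (time, channel, wavelength)")
        if self.intensities.shape[1] != self.montage.n_channels:
            raise DataError(
                f"{self.intensities.shape[1]} data channels vs "
                f"{self.montage.n_channels} montage channels"
            )
        if self.intensities.shape[2] != len(self.wavelengths):
            raise DataError("wavelength axis does not match wavelengths tuple")
        if self.stage == "intensity" and np.any(self.intensities <= 0):
            ch = int(np.argwhere(np.any(self.intensities <= 0, axis=(0, 2)))[0, 0])
            raise DataError(f"non-positive intensity in channel {ch}")
        dur = self.duration
        for onset, duration, _ in self.annotations:
            if onset < 0 or onset + duration > dur + 1e-9:
                raise DataError("annotation interval outside recording")

    @property
    def n_times(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sampling_rate

    def copy_with(self, data: np.ndarray, stage: str, **kw) -> "OpticalRecording":
        out = replace(self, intensities=data, stage=stage, **kw)
        out.bad_channels = set(self.bad_channels) | set(kw.get("bad_channels", set()))
        return out


@dataclass
class HemoRecording:
    """HbO/HbR concentration-change series in µM (time x channel).

    After the retention step only long-separation channels remain;
    ``channel_names`` and ``bad_channels`` refer to those channels.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None  # midpoints, cm
    bad_channels: set[int] = field(default_factory=set)
    annotations: list[Annotation] = field(default_factory=list)
    stage: str = "hemo"

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise DataError("hbo and hbr must have identical shape")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.hbo.shape[1])]

    @property
    def n_times(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.sampling_rate

    def copy_with(self, hbo: np.ndarray, hbr: np.ndarray, stage: str) -> "HemoRecording":
        return replace(self, hbo=hbo, hbr=hbr, stage=stage)
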