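"""Synthetic fNIRS data with known ground truth.

Generates (i) latent connectivity networks, (ii) HbO/HbR concentration
series whose low-frequency correlations realize the latent network,
(iii) raw dual-wavelength optical intensities by inverting the modified
Beer-Lambert law, with superficial (scalp) contamination, motion
artifacts and saturation episodes, and (iv) long-format degree-count
tables drawn from the multilevel Poisson generative model with known
coefficients.  All randomness is driven by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError, ParameterError
from .glmm import (
    GROUP_LEVELS,
    SESSION_LEVELS,
    ModelParameters,
    fixed_design,
)
from .montage import frontal_montage
from .preprocess import BeerLambertConfig, hemo_to_od
from .recording import HemoRecording, OpticalRecording

__all__ = [
    "LatentNetwork",
    "SimulationConfig",
    "simulate_latent_network",
    "simulate_cluster_network",
    "simulate_hemo",
    "simulate_optical",
    "simulate_degree_dataset",
]


# --------------------------------------------------------------------------
# latent network
# --------------------------------------------------------------------------

@dataclass
class LatentNetwork:
    """Ground-truth functional network among long channels.

    ``adjacency`` is a symmetric 0/1 matrix with zero diagonal;
    ``coupling`` holds the per-edge coupling strength in (0, 1]
    (defined only where adjacency is 1, zero elsewhere).
    """

    n_channels: int
    adjacency: np.ndarray
    coupling: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.shape != (self.n_channels, self.n_channels):
            raise ParameterError("adjacency shape mismatch")
        if not np.array_equal(A, A.T):
            raise ParameterError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ParameterError("adjacency diagonal must be zero")
        if not set(np.unique(A)).issubset({0, 1}):
            raise ParameterError("adjacency must be binary")
        C = np.asarray(self.coupling, float)
        if np.any((A == 1) & ((C <= 0) | (C > 1))):
            raise ParameterError("coupling on edges must lie in (0, 1]")
        self.adjacency = A.astype(int)
        self.coupling = np.where(A == 1, C, 0.0)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def simulate_latent_network(
    n_channels: int,
    edge_probability: float,
    seed: int | None = None,
    coupling: float | tuple[float, float] = (0.5, 1.0),
) -> LatentNetwork:
    """Erdos-Renyi-style random network with per-edge coupling strengths.

    ``coupling`` is either a fixed strength or a (low, high] range to
    draw uniformly per edge.
    """
    if not 0.0 <= edge_probability <= 1.0:
        raise ParameterError("edge_probability must lie in [0, 1]")
    if n_channels < 2:
        raise ParameterError("need at least 2 channels")
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n_channels, n_channels)) < edge_probability, k=1)
    A = (upper | upper.T).astype(int)
    if np.isscalar(coupling):
        C = np.full_like(A, float(coupling), dtype=float)
    else:
        lo, hi = coupling
        Cu = np.triu(rng.uniform(lo, hi, (n_channels, n_channels)), k=1)
        C = Cu + Cu.T
    return LatentNetwork(n_channels, A, np.where(A == 1, C, 0.0))


def simulate_cluster_network(
    n_channels: int,
    n_clusters: int,
    seed: int | None = None,
    coupling: float | tuple[float, float] = (0.6, 0.9),
) -> LatentNetwork:
    """Latent network of disjoint clusters (cliques) of channels.

    Channels are randomly partitioned into ``n_clusters`` near-equal
    communities and fully connected within each; such block structure
    is jointly realizable at high coupling, so it produces the high
    node degrees typical of resting-state graphs (larger clusters mean
    higher degree).
    """
    if n_clusters < 1 or n_clusters > n_channels:
        raise ParameterError("n_clusters must lie in [1, n_channels]")
    rng = np.random.default_rng(seed)
    labels = np.sort(np.arange(n_channels) % n_clusters)
    rng.shuffle(labels)
    A = (labels[:, None] == labels[None, :]).astype(int)
    np.fill_diagonal(A, 0)
    if np.isscalar(coupling):
        C = np.full((n_channels, n_channels), float(coupling))
    else:
        # one coupling per cluster, shared by its edges (keeps the
        # within-cluster correlation target jointly realizable)
        percluster = rng.uniform(*coupling, size=n_clusters)
        C = np.minimum.outer(percluster[labels], percluster[labels])
    return LatentNetwork(n_channels, A, np.where(A == 1, C, 0.0))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Acquisition and signal-structure parameters of the simulator.

    Defaults emulate a frontal continuous-wave acquisition: 44 long
    channels (~3.5 cm separation), 8 short channels (~0.76 cm), two
    wavelengths (760/850 nm) sampled at 5.1 Hz, with cardiac
    (1-1.5 Hz), respiratory (0.2-0.5 Hz) and Mayer-wave (~0.1 Hz)
    oscillations superimposed on the neural signal.  Amplitudes are in
    µM of HbO-equivalent concentration change.
    """

    sampling_rate: float = 5.1
    duration: float = 300.0
    wavelengths: tuple[float, float] = (760.0, 850.0)
    n_long_channels: int = 44
    n_short_channels: int = 8
    long_separation: float = 3.5
    short_separation: float = 0.76
    cardiac_band: tuple[float, float] = (1.0, 1.5)
    respiration_band: tuple[float, float] = (0.2, 0.5)
    mayer_freq: float = 0.1
    artifact_rate: float = 1.0       # motion events per minute
    saturation_rate: float = 0.0     # saturation episodes per recording
    seed: int | None = None
    # signal-structure knobs
    hemo_amplitude: float = 0.5      # SD of neural HbO, µM
    noise_sd: float = 0.25           # channel noise SD relative to hemo_amplitude
    cardiac_amp: float = 0.2         # µM
    respiration_amp: float = 0.15    # µM
    mayer_amp: float = 0.1           # µM
    hbr_ratio: float = -0.4
    hbr_noise_sd: float = 0.1        # relative to |hbr_ratio| * hemo_amplitude
    hbr_lag_s: float = 0.0
    physio_hbr_ratio: float = 0.3    # blood-volume oscillations co-vary in HbR
    superficial_weight: float = 0.3  # relative contribution to long channels
    baseline_intensity: float = 1.0  # arbitrary units
    intensity_noise: float = 0.003   # relative instrument noise SD (white)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 0.20:
            raise ConfigurationError("sampling rate must exceed twice the analysis band")
        for name in ("duration", "n_long_channels", "n_short_channels"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def n_times(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _band_limited_noise(
    rng: np.random.Generator, n_times: int, n_series: int, fs: float,
    band: tuple[float, float] = (0.01, 0.2),
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` (columns = series)."""
    x = rng.standard_normal((n_times, n_series))
    nyq = fs / 2.0
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.99)
    b, a = signal.butter(4, [lo, hi], btype="band")
    y = signal.filtfilt(b, a, x, axis=0)
    sd = y.std(axis=0)
    sd[sd == 0] = 1.0
    return y / sd


def _jittered_oscillation(
    rng: np.random.Generator, t: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Unit-amplitude sinusoid with random frequency, phase and slow drift."""
    f = rng.uniform(*band)
    phase = rng.uniform(0, 2 * np.pi)
    # random phase modulation so independent oscillators decorrelate well
    # within a recording instead of beating against each other
    drift = np.cumsum(rng.normal(0, 0.08, t.size))
    return np.sin(2 * np.pi * f * t + phase + drift)


# --------------------------------------------------------------------------
# hemodynamic simulation
# --------------------------------------------------------------------------

def _mixing_matrix(network: LatentNetwork) -> np.ndarray:
    """Cholesky-style mixing realizing the target edge correlations.

    The target correlation matrix is identity plus coupling on the
    edges.  When the graph makes that target indefinite (correlation
    constraints can be mutually infeasible) its spectrum is clipped at
    zero and the diagonal renormalized, which shrinks realized
    correlations toward feasibility while preserving their ordering.
    """
    R = np.eye(network.n_channels) + network.coupling
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < 1e-10:
        vals = np.clip(vals, 1e-10, None)
        R = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return np.linalg.cholesky(R + 1e-9 * np.eye(len(R)))


def simulate_hemo(network: LatentNetwork, config: SimulationConfig) -> HemoRecording:
    """Generate HbO/HbR series realizing the latent network.

    Coupled channels share low-frequency (0.01-0.2 Hz) common
    components mixed so that the expected correlation of an edge equals
    its coupling strength (shrunk toward feasibility when the requested
    pattern is not jointly realizable).  HbR is a negatively scaled
    (optionally lagged) copy of HbO plus independent noise; cardiac,
    respiratory and Mayer oscillations with per-channel jittered
    frequency and phase are superimposed on both.
    """
    if network.n_channels != config.n_long_channels:
        raise ParameterError(
            f"network has {network.n_channels} channels, config expects "
            f"{config.n_long_channels}"
        )
    rng = np.random.default_rng(config.seed)
    n = network.n_channels
    T = config.n_times
    t = np.arange(T) / config.sampling_rate
    fs = config.sampling_rate

    sources = _band_limited_noise(rng, T, n, fs)
    neural = sources @ _mixing_matrix(network).T

    hbo = config.hemo_amplitude * neural
    if config.noise_sd > 0:
        hbo = hbo + (
            config.hemo_amplitude
            * config.noise_sd
            * _band_limited_noise(rng, T, n, fs, band=(0.01, min(1.0, fs / 2 * 0.9)))
        )

    # HbR: negatively scaled, optionally lagged copy of the neural HbO
    lagged = hbo
    if config.hbr_lag_s > 0:
        shift = int(round(config.hbr_lag_s * fs))
        lagged = np.roll(hbo, shift, axis=0)
        lagged[:shift] = hbo[:shift]
    hbr = config.hbr_ratio * lagged
    if config.hbr_noise_sd > 0:
        hbr = hbr + (
            abs(config.hbr_ratio)
            * config.hemo_amplitude
            * config.hbr_noise_sd
            * _band_limited_noise(rng, T, n, fs)
        )

    # physiological oscillations, jittered per channel; these are
    # blood-volume effects, so HbO and HbR co-vary (positive ratio),
    # unlike the anti-correlated neural component
    for c in range(n):
        osc = np.zeros(T)
        if config.cardiac_amp > 0:
            osc += config.cardiac_amp * _jittered_oscillation(rng, t, config.cardiac_band)
        if config.respiration_amp > 0:
            osc += config.respiration_amp * _jittered_oscillation(
                rng, t, config.respiration_band
            )
        if config.mayer_amp > 0:
            osc += config.mayer_amp * _jittered_oscillation(
                rng, t, (0.9 * config.mayer_freq, 1.1 * config.mayer_freq)
            )
        hbo[:, c] += osc
        hbr[:, c] += config.physio_hbr_ratio * osc

    return HemoRecording(
        hbo=hbo,
        hbr=hbr,
        sampling_rate=fs,
        channel_names=[f"ch{i}" for i in range(n)],
        stage="hemo",
    )


# --------------------------------------------------------------------------
# optical forward model
# --------------------------------------------------------------------------

def simulate_optical(
    hemo: HemoRecording,
    config: SimulationConfig,
    beerlambert: BeerLambertConfig | None = None,
    return_truth: bool = False,
) -> OpticalRecording | tuple[OpticalRecording, dict]:
    """Forward-model raw intensities from concentration series.

    Long channels carry the supplied HbO/HbR plus a superficial (scalp)
    component shared with the nearest short channel's region; short
    channels carry the superficial component only (plus small noise).
    Optical density is the Beer-Lambert forward transform; intensities
    are baseline * 10^(-OD).  Motion artifacts (half 1-s half-cosine
    spikes, half baseline shifts, amplitude 5-20x the channel OD SD)
    arrive at ``artifact_rate`` per minute; saturation episodes add a
    large concentration excursion so reconstructed HbO exceeds the
    saturation threshold.

    With ``return_truth`` the ground truth (montage, superficial series,
    artifact and saturation windows) is returned alongside.
    """
    beerlambert = beerlambert or BeerLambertConfig(wavelengths=config.wavelengths)
    if abs(np.linalg.det(beerlambert.extinction)) < 1e-12:
        raise ConfigurationError("extinction matrix is singular")
    if hemo.n_channels != config.n_long_channels:
        raise ParameterError("hemo channel count does not match config")
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1_000_003
    )
    T = hemo.n_times
    fs = config.sampling_rate

    montage = frontal_montage(
        n_long=config.n_long_channels,
        n_short=config.n_short_channels,
        long_separation=config.long_separation,
        short_separation=config.short_separation,
        seed=None if config.seed is None else config.seed + 7,
    )
    long_ix = montage.long_indices()
    short_ix = montage.short_indices()
    n_total = montage.n_channels

    # one superficial process per scalp region (= per short channel);
    # long channels join the region of their nearest short channel.
    # Scalp hemodynamics pulse strongly, so each regional process also
    # carries cardiac/respiratory/Mayer oscillations.
    n_regions = max(len(short_ix), 1)
    t = np.arange(T) / fs
    if config.superficial_weight > 0:
        superficial = _band_limited_noise(rng, T, n_regions, fs, band=(0.01, 0.5))
    else:
        superficial = np.zeros((T, n_regions))
    amp = config.hemo_amplitude
    for k in range(n_regions if config.superficial_weight > 0 else 0):
        if config.cardiac_amp > 0:
            superficial[:, k] += (
                1.5 * config.cardiac_amp / amp
            ) * _jittered_oscillation(rng, t, config.cardiac_band)
        if config.respiration_amp > 0:
            superficial[:, k] += (
                config.respiration_amp / amp
            ) * _jittered_oscillation(rng, t, config.respiration_band)
        if config.mayer_amp > 0:
            superficial[:, k] += (config.mayer_amp / amp) * _jittered_oscillation(
                rng, t, (0.9 * config.mayer_freq, 1.1 * config.mayer_freq)
            )
    mid = montage.midpoints
    region_of_long = np.zeros(len(long_ix), dtype=int)
    if len(short_ix):
        for k, li in enumerate(long_ix):
            region_of_long[k] = int(
                np.argmin(np.linalg.norm(mid[short_ix] - mid[li], axis=1))
            )

    hbo = np.zeros((T, n_total))
    hbr = np.zeros((T, n_total))
    amp = config.hemo_amplitude
    w_sup = config.superficial_weight
    hbo[:, long_ix] = hemo.hbo + w_sup * amp * superficial[:, region_of_long]
    hbr[:, long_ix] = hemo.hbr + config.physio_hbr_ratio * w_sup * amp * superficial[:, region_of_long]
    if len(short_ix) and config.superficial_weight > 0:
        sup_short = superficial + 0.05 * rng.standard_normal((T, n_regions))
        hbo[:, short_ix] = amp * sup_short
        hbr[:, short_ix] = config.physio_hbr_ratio * amp * sup_short

    od = hemo_to_od(hbo, hbr, montage.separations, beerlambert)  # (T, C, 2)

    # motion artifacts: global events, per-channel amplitude
    artifact_windows: list[tuple[float, float, str]] = []
    n_events = rng.poisson(config.artifact_rate * config.duration / 60.0)
    od_sd = od.std(axis=0)  # (C, 2)
    od_sd[od_sd == 0] = np.median(od_sd[od_sd > 0]) if np.any(od_sd > 0) else 1e-4
    for _ in range(n_events):
        onset = rng.uniform(0.0, max(config.duration - 1.0, 0.0))
        i0 = int(onset * fs)
        kind = "spike" if rng.random() < 0.5 else "shift"
        # motion moves the whole probe: per-channel amplitude, but the same
        # sign and gain at both wavelengths
        gain = (
            rng.uniform(5.0, 20.0, size=(od_sd.shape[0], 1))
            * rng.choice([-1.0, 1.0], (od_sd.shape[0], 1))
        ) * np.ones((1, od_sd.shape[1]))
        if kind == "spike":
            width = int(round(1.0 * fs))
            i1 = min(i0 + width, T)
            pulse = np.sin(np.pi * np.arange(i1 - i0) / max(width, 1))  # half cosine lobe
            od[i0:i1] += pulse[:, None, None] * gain[None, :, :] * od_sd[None, :, :]
            artifact_windows.append((onset, (i1 - i0) / fs, kind))
        else:
            od[i0:] += gain[None, :, :] * od_sd[None, :, :]
            artifact_windows.append((onset, 1.0 / fs, kind))

    # saturation episodes: large HbO excursion in one long channel
    saturation_windows: list[tuple[float, float, int]] = []
    n_sat = rng.poisson(config.saturation_rate)
    for _ in range(n_sat):
        onset = rng.uniform(0.0, max(config.duration - 5.0, 0.0))
        i0, i1 = int(onset * fs), min(int((onset + 5.0) * fs), T)
        ch = int(rng.choice(long_ix))
        bump = 30.0 * np.sin(np.pi * np.arange(i1 - i0) / max(i1 - i0, 1)) ** 2  # µM
        extra_od = hemo_to_od(
            bump[:, None], np.zeros((i1 - i0, 1)),
            montage.separations[[ch]], beerlambert,
        )
        od[i0:i1, ch, :] += extra_od[:, 0, :]
        saturation_windows.append((onset, (i1 - i0) / fs, ch))

    # white instrument noise, expressed in OD so it is multiplicative in
    # intensity; its temporal derivative dominates the smooth hemodynamic
    # derivative, as in real continuous-wave recordings.  Shorter channels
    # receive more light, so their relative noise is proportionally lower.
    if config.intensity_noise > 0:
        rel = montage.separations / config.long_separation
        od = od + (
            (config.intensity_noise / np.log(10.0))
            * rel[None, :, None]
            * rng.standard_normal(od.shape)
        )

    intensities = config.baseline_intensity * 10.0 ** (-od)
    rec = OpticalRecording(
        intensities=intensities,
        sampling_rate=fs,
        montage=montage,
        wavelengths=config.wavelengths,
        stage="intensity",
    )
    if not return_truth:
        return rec
    truth = {
        "montage": montage,
        "superficial": superficial,
        "region_of_long": region_of_long,
        "artifact_windows": artifact_windows,
        "saturation_windows": saturation_windows,
        "hbo_total": hbo,
        "hbr_total": hbr,
    }
    return rec, truth


# --------------------------------------------------------------------------
# degree-count generative model
# --------------------------------------------------------------------------

def simulate_degree_dataset(
    params: ModelParameters,
    n_per_group: tuple[int, int, int],
    n_channels: int = 44,
    seed: int | None = None,
    clip: bool = False,
    return_truth: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Draw a degree table from the multilevel Poisson model.

    ``n_per_group`` gives participant counts for (Sham, DLPFC, VLPFC).
    Counts follow the unbounded Poisson likelihood by default, matching
    the model as specified; ``clip`` truncates them to the graph bound
    [0, n_channels - 1] for extra realism.  With ``return_truth`` the
    sampled random effects are returned alongside.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, 1.0, (n_channels, 9)) * params.sigma_u[np.array([0, 1, 1, 2, 2, 3, 3, 3, 3])]
    n_participants = sum(n_per_group)
    w = rng.normal(0.0, 1.0, (n_participants, 3)) * params.sigma_w

    rows = []
    pid = 0
    for g, n_g in zip(GROUP_LEVELS, n_per_group):
        for _ in range(n_g):
            pname = f"P{pid:03d}"
            for s in SESSION_LEVELS:
                for c in range(n_channels):
                    rows.append((pname, g, s, f"ch{c:02d}", pid, c))
            pid += 1
    df = pd.DataFrame(
        rows, columns=["participant", "group", "session", "channel", "_p", "_c"]
    )
    X = fixed_design(df)
    eta = X @ params.beta
    eta += np.einsum("nk,nk->n", X, u[df["_c"].to_numpy()])
    eta += np.einsum("nk,nk->n", X[:, [0, 3, 4]], w[df["_p"].to_numpy()])
    y = rng.poisson(np.exp(eta))
    if clip:
        y = np.clip(y, 0, n_channels - 1)
    df["degree"] = y
    df = df.drop(columns=["_p", "_c"])
    if not return_truth:
        return df
    return df, {"u": u, "w": w, "eta": eta}
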