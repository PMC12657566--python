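"""Preprocessing chain: raw intensities to clean HbO/HbR series.

The chain order is fixed and enforced through the recording's ``stage``
tag::

    intensity -> OD -> TDDR -> short-channel regression -> SCI screening
              -> spherical-spline interpolation of bad channels
              -> modified Beer-Lambert -> negative-correlation
                 enhancement -> band-pass (0.01-0.20 Hz)

Each operation accepts input from any *earlier* stage (so that single
stages can be exercised in isolation) but refuses input from its own or
a later stage.  No operation changes the number of time samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .errors import ConfigurationError, DataError, ParameterError
from .montage import Montage
from .recording import HemoRecording, OpticalRecording, check_stage

logger = logging.getLogger(__name__)

_OD_STAGES = ("od", "od_tddr", "od_ssr", "od_interp")

_emitted_warnings: set[str] = set()


def _warn_once(message: str) -> None:
    # filter-design notes repeat identically for every recording of a
    # cohort; log each distinct message once per process
    if message not in _emitted_warnings:
        _emitted_warnings.add(message)
        logger.warning(message)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_extinction_table() -> dict[float, tuple[float, float]]:
    """Tabulated molar extinction coefficients (cm^-1 M^-1, base 10).

    Returns a mapping wavelength_nm -> (eps_HbO, eps_HbR).
    """
    table = {}
    path = resources.files("nirsconn.data") / "extinction_coefficients.csv"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("wavelength"):
            continue
        wl, hbo, hbr = line.split(",")
        table[float(wl)] = (float(hbo), float(hbr))
    return table


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2x2 extinction matrix, rows = wavelengths, cols = (HbO, HbR)."""
    table = load_extinction_table()
    rows = []
    for wl in wavelengths:
        if wl not in table:
            raise ConfigurationError(f"no tabulated extinction at {wl} nm")
        rows.append(table[wl])
    return np.array(rows, dtype=float)


@dataclass
class BeerLambertConfig:
    """Modified Beer-Lambert conversion parameters.

    ``ppf`` is the partial pathlength factor per wavelength; the product
    separation x ppf is treated as the total effective photon path.
    """

    ppf: tuple[float, float] = (6.0, 6.0)
    extinction: np.ndarray | None = None  # (wavelength, chromophore)
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.ppf):
            raise ConfigurationError("ppf must be positive")
        if self.extinction is None:
            self.extinction = extinction_matrix(self.wavelengths)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")


@dataclass
class QualityConfig:
    """Channel-quality and filtering parameters.

    ``sci_threshold``: channels with scalp coupling index strictly below
    this are marked bad.  ``filter_band`` and ``transition_widths`` (low,
    high) define the analysis band-pass.
    """

    sci_threshold: float = 0.7
    cardiac_band: tuple[float, float] = (0.7, 1.5)
    filter_band: tuple[float, float] = (0.01, 0.20)
    transition_widths: tuple[float, float] = (0.01, 0.2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.sci_threshold <= 1.0:
            raise ParameterError("sci_threshold must lie in [0, 1]")
        if not self.cardiac_band[0] < self.cardiac_band[1]:
            raise ParameterError("cardiac_band edges must be ordered")
        if not self.filter_band[0] < self.filter_band[1]:
            raise ParameterError("filter_band edges must be ordered")


# --------------------------------------------------------------------------
# optical density
# --------------------------------------------------------------------------

def intensity_to_od(rec: OpticalRecording) -> OpticalRecording:
    """Convert raw intensities to optical density.

    OD(t) = -log10(I(t) / mean_t I), per channel and wavelength, so each
    series has mean OD ~ 0 around its own temporal baseline.
    """
    check_stage(rec.stage, ("intensity",), "intensity_to_od")
    if np.any(rec.intensities <= 0):
        ch = int(np.argwhere(np.any(rec.intensities <= 0, axis=(0, 2)))[0, 0])
        raise DataError(f"non-positive intensity in channel {ch}")
    baseline = rec.intensities.mean(axis=0, keepdims=True)
    od = -np.log10(rec.intensities / baseline)
    return rec.copy_with(od, "od")


# --------------------------------------------------------------------------
# TDDR motion correction
# --------------------------------------------------------------------------

def tddr(series: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Temporal derivative distribution repair of a single series.

    Robustly re-weights the temporal derivative of the low-frequency
    (< 0.5 Hz) component with Tukey's biweight (tuning constant 4.685),
    iterating mean/weight estimation to convergence, re-integrates the
    weighted derivative, and restores the untouched high-frequency
    component and mean.  Output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise DataError("tddr needs a 1-D series of length >= 3")
    if not np.all(np.isfinite(x)):
        raise DataError("tddr input contains non-finite samples")

    mean = x.mean()
    x = x - mean
    # split at 0.5 Hz: only the slow component is repaired
    fc = 0.5 * 2.0 / sampling_rate
    if fc < 1.0:
        b, a = signal.butter(3, fc)
        low = signal.filtfilt(b, a, x, padlen=0)
    else:
        low = x
    high = x - low

    deriv = np.diff(low)
    tune = 4.685
    w = np.ones_like(deriv)
    mu = 0.0
    for _ in range(50):
        mu = np.sum(w * deriv) / np.sum(w)
        dev = np.abs(deriv - mu)
        sigma = 1.4826 * np.median(dev)
        if sigma == 0.0:
            w_new = np.ones_like(deriv)
        else:
            r = dev / (sigma * tune)
            w_new = np.square(np.clip(1.0 - r**2, 0.0, None)) * (r < 1.0)
        if np.max(np.abs(w_new - w)) < 1e-8:
            w = w_new
            break
        w = w_new

    corrected = np.concatenate([[0.0], np.cumsum(w * (deriv - mu))])
    corrected -= corrected.mean()
    return corrected + high + mean


def tddr_recording(rec: OpticalRecording) -> OpticalRecording:
    """Apply TDDR to every channel and wavelength of an OD recording."""
    check_stage(rec.stage, ("od",), "tddr")
    out = np.empty_like(rec.intensities)
    for c in range(rec.n_channels):
        for w in range(rec.intensities.shape[2]):
            out[:, c, w] = tddr(rec.intensities[:, c, w], rec.sampling_rate)
    return rec.copy_with(out, "od_tddr")


# --------------------------------------------------------------------------
# short-separation channel regression
# --------------------------------------------------------------------------

def pair_short_channels(montage: Montage) -> dict[int, int]:
    """Map each long channel to its spatially nearest short channel."""
    long_ix = montage.long_indices()
    short_ix = montage.short_indices()
    if short_ix.size == 0:
        raise ConfigurationError("montage contains no short channels")
    mid = montage.midpoints
    pairing = {}
    for li in long_ix:
        d = np.linalg.norm(mid[short_ix] - mid[li], axis=1)
        pairing[int(li)] = int(short_ix[np.argmin(d)])
    return pairing


def short_channel_regress(rec: OpticalRecording) -> OpticalRecording:
    """Regress the paired short channel out of each long channel.

    Per long channel and wavelength the least-squares projection onto
    ``[1, short]`` is subtracted, leaving a residual orthogonal to the
    short-channel regressor.  Short channels pass through unchanged.
    """
    check_stage(rec.stage, ("od", "od_tddr"), "short_channel_regress")
    pairing = pair_short_channels(rec.montage)
    out = rec.intensities.copy()
    for li, si in pairing.items():
        for w in range(rec.intensities.shape[2]):
            y = rec.intensities[:, li, w]
            s = rec.intensities[:, si, w]
            X = np.column_stack([np.ones_like(s), s])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            out[:, li, w] = y - X @ coef
    return rec.copy_with(out, "od_ssr")


# --------------------------------------------------------------------------
# scalp coupling index
# --------------------------------------------------------------------------

def scalp_coupling_index(rec: OpticalRecording, q: QualityConfig | None = None) -> np.ndarray:
    """Per-channel SCI: cardiac-band inter-wavelength correlation.

    Both wavelengths' series are band-passed to the cardiac band and the
    zero-lag Pearson correlation is returned.  Channels whose filtered
    signal has zero variance get SCI = nan (flagged bad downstream).
    """
    q = q or QualityConfig()
    check_stage(rec.stage, _OD_STAGES, "scalp_coupling_index")
    lo, hi = q.cardiac_band
    if rec.duration < 10.0 / lo:
        raise DataError("recording shorter than 10 cardiac periods")
    nyq = rec.sampling_rate / 2.0
    hi = min(hi, 0.98 * nyq)
    b, a = signal.butter(4, [lo / nyq, hi / nyq], btype="band")
    sci = np.empty(rec.n_channels)
    for c in range(rec.n_channels):
        f0 = signal.filtfilt(b, a, rec.intensities[:, c, 0])
        f1 = signal.filtfilt(b, a, rec.intensities[:, c, 1])
        if f0.std() == 0.0 or f1.std() == 0.0:
            warnings.warn(f"SCI undefined for zero-variance channel {c}", stacklevel=2)
            sci[c] = np.nan
            continue
        sci[c] = np.corrcoef(f0, f1)[0, 1]
    return sci


def flag_bad_channels(sci: np.ndarray, threshold: float = 0.7) -> set[int]:
    """Channels with SCI strictly below the threshold (or undefined)."""
    bad = {int(c) for c in np.flatnonzero(np.isnan(sci))}
    bad |= {int(c) for c in np.flatnonzero(sci < threshold)}
    return bad


# --------------------------------------------------------------------------
# spherical-spline interpolation of bad channels
# --------------------------------------------------------------------------

def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    # least-squares sphere: |x|^2 = 2 x.c + (r^2 - |c|^2)
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    bvec = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def _spline_g(cosang: np.ndarray, order: int = 4, n_terms: int = 7) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n * (n + 1.0)) ** order
    full = np.zeros(n_terms + 1)
    full[1:] = coef
    return legendre.legval(cosang, full) / (4.0 * np.pi)


def interpolate_bad_channels(
    rec: OpticalRecording,
    bad: set[int] | None = None,
    order: int = 4,
    n_terms: int = 7,
    reg: float = 1e-5,
) -> OpticalRecording:
    """Replace bad channels by a spherical-spline estimate.

    Channel midpoints are projected onto a best-fit sphere and a
    spherical spline (order ``order``, ``n_terms`` Legendre terms,
    Tikhonov regularization ``reg``) over good channels is evaluated at
    bad-channel positions, time point by time point.  Good channels are
    untouched; an empty bad set is the identity.
    """
    check_stage(rec.stage, _OD_STAGES, "interpolate_bad_channels")
    bad = set(rec.bad_channels if bad is None else bad)
    if not bad:
        return rec.copy_with(rec.intensities.copy(), "od_interp")
    good = sorted(set(range(rec.n_channels)) - bad)
    if len(good) < 3:
        raise DataError("spherical-spline interpolation needs >= 3 good channels")
    bad_list = sorted(bad)

    mid = rec.montage.midpoints
    center, radius = _fit_sphere(mid)
    unit = (mid - center) / np.linalg.norm(mid - center, axis=1, keepdims=True)

    cos_gg = np.clip(unit[good] @ unit[good].T, -1.0, 1.0)
    cos_bg = np.clip(unit[bad_list] @ unit[good].T, -1.0, 1.0)
    G = _spline_g(cos_gg, order, n_terms) + reg * np.eye(len(good))
    Gb = _spline_g(cos_bg, order, n_terms)

    k = len(good)
    C = np.zeros((k + 1, k + 1))
    C[:k, :k] = G
    C[:k, k] = 1.0
    C[k, :k] = 1.0

    out = rec.intensities.copy()
    for w in range(rec.intensities.shape[2]):
        V = rec.intensities[:, good, w].T  # (k, T)
        rhs = np.vstack([V, np.zeros((1, V.shape[1]))])
        sol = np.linalg.solve(C, rhs)
        c_coef, d_coef = sol[:k], sol[k]
        out[:, bad_list, w] = (Gb @ c_coef + d_coef).T
    return rec.copy_with(out, "od_interp")


# --------------------------------------------------------------------------
# modified Beer-Lambert law
# --------------------------------------------------------------------------

def hemo_to_od(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    separations: np.ndarray,
    blc: BeerLambertConfig,
) -> np.ndarray:
    """Forward modified Beer-Lambert: concentrations (µM) to OD.

    dOD(lambda) = (eps_HbO dHbO + eps_HbR dHbR) * d * ppf(lambda), with
    concentrations in mol/L and the separation d in cm.
    """
    conc = np.stack([hbo_um, hbr_um], axis=-1) * 1e-6  # (T, C, 2) in M
    od = np.einsum("tcj,wj->tcw", conc, blc.extinction)
    path = separations[None, :, None] * np.asarray(blc.ppf)[None, None, :]
    return od * path


def od_to_hemo(rec: OpticalRecording, blc: BeerLambertConfig | None = None) -> HemoRecording:
    """Invert the modified Beer-Lambert law channel by channel.

    [dHbO, dHbR]^T = E^-1 [dOD_l1/(d ppf_1), dOD_l2/(d ppf_2)]^T, output
    in µM.  Only long-separation channels are retained for analysis.
    """
    blc = blc or BeerLambertConfig(wavelengths=rec.wavelengths)
    check_stage(rec.stage, _OD_STAGES, "od_to_hemo")
    sep = rec.montage.separations
    if np.any(sep <= 0):
        raise ConfigurationError("unknown or non-positive channel separation")
    Einv = np.linalg.inv(blc.extinction)
    path = sep[None, :, None] * np.asarray(blc.ppf)[None, None, :]  # (1, C, 2)
    scaled = rec.intensities / path
    conc = np.einsum("jw,tcw->tcj", Einv, scaled) * 1e6  # µM

    long_ix = rec.montage.long_indices()
    names = [rec.montage.channel_names[i] for i in long_ix]
    long_pos = rec.montage.midpoints[long_ix]
    remap = {int(old): new for new, old in enumerate(long_ix)}
    bad = {remap[b] for b in rec.bad_channels if b in remap}
    return HemoRecording(
        hbo=conc[:, long_ix, 0],
        hbr=conc[:, long_ix, 1],
        sampling_rate=rec.sampling_rate,
        channel_names=names,
        channel_positions=long_pos,
        bad_channels=bad,
        annotations=list(rec.annotations),
        stage="hemo",
    )


# --------------------------------------------------------------------------
# negative-correlation enhancement
# --------------------------------------------------------------------------

def negative_correlation_enhance(hemo: HemoRecording) -> HemoRecording:
    """Enforce HbO/HbR anti-correlation channel-wise.

    x' = (x - (sx/sy) y) / 2 and y' = (y - (sy/sx) x) / 2 with x = HbO,
    y = HbR and s the respective standard deviations; the outputs
    satisfy corr(x', y') = -1 exactly.  Zero-variance channels are
    skipped with a warning.
    """
    check_stage(hemo.stage, ("hemo",), "negative_correlation_enhance")
    hbo = hemo.hbo.copy()
    hbr = hemo.hbr.copy()
    for c in range(hemo.n_channels):
        x, y = hemo.hbo[:, c], hemo.hbr[:, c]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            warnings.warn(f"zero variance in channel {c}; enhancement skipped", stacklevel=2)
            continue
        hbo[:, c] = 0.5 * (x - (sx / sy) * y)
        hbr[:, c] = 0.5 * (y - (sy / sx) * x)
    return hemo.copy_with(hbo, hbr, "hemo_enhanced")


# --------------------------------------------------------------------------
# band-pass filter
# --------------------------------------------------------------------------

def design_bandpass(
    sampling_rate: float,
    n_times: int,
    q: QualityConfig | None = None,
) -> np.ndarray:
    """Windowed-sinc FIR band-pass taps (Hamming window, zero phase use).

    The filter length follows the Hamming-window rule
    ``numtaps ~ 3.3 fs / transition`` for the narrower transition band,
    capped below the signal length; the -6 dB points sit at the stated
    band edges (cutoffs are edge +/- transition/2).
    """
    q = q or QualityConfig()
    lo, hi = q.filter_band
    tw_lo, tw_hi = q.transition_widths
    nyq = sampling_rate / 2.0
    if hi >= nyq:
        raise ConfigurationError("upper cutoff at or above Nyquist")
    if tw_hi >= hi:
        _warn_once(
            f"upper transition width {tw_hi:g} Hz is as wide as the upper "
            f"cutoff {hi:g} Hz; applying literally"
        )
    numtaps = int(np.ceil(3.3 * sampling_rate / min(tw_lo, tw_hi)))
    max_taps = max(3, n_times - 1)
    if numtaps > max_taps:
        _warn_once(f"FIR length {numtaps} capped at {max_taps} (signal length)")
        numtaps = max_taps
    if numtaps % 2 == 0:
        numtaps -= 1
    edges = [max(lo - tw_lo / 2.0, 1e-4), min(hi + tw_hi / 2.0, 0.99 * nyq)]
    return signal.firwin(numtaps, edges, pass_zero=False, window="hamming", fs=sampling_rate)


def bandpass(hemo: HemoRecording, q: QualityConfig | None = None) -> HemoRecording:
    """Zero-phase FIR band-pass of HbO and HbR (default 0.01-0.20 Hz)."""
    q = q or QualityConfig()
    check_stage(hemo.stage, ("hemo", "hemo_enhanced"), "bandpass")
    if hemo.sampling_rate <= 2.0 * q.filter_band[1]:
        raise ConfigurationError("sampling rate must exceed twice the upper cutoff")
    taps = design_bandpass(hemo.sampling_rate, hemo.n_times, q)
    padlen = min(3 * len(taps), hemo.n_times - 1)
    hbo = signal.filtfilt(taps, 1.0, hemo.hbo, axis=0, padlen=padlen)
    hbr = signal.filtfilt(taps, 1.0, hemo.hbr, axis=0, padlen=padlen)
    return hemo.copy_with(hbo, hbr, "hemo_filtered")


# --------------------------------------------------------------------------
# full chain
# --------------------------------------------------------------------------

def preprocess_recording(
    rec: OpticalRecording,
    blc: BeerLambertConfig | None = None,
    quality: QualityConfig | None = None,
    annotations: list[tuple[float, float, str]] | None = None,
    apply_tddr: bool = True,
) -> tuple[HemoRecording, dict]:
    """Run the full preprocessing chain in its mandatory order.

    Returns the analysis-ready :class:`HemoRecording` (long channels
    only, band-passed) and a per-stage report with the SCI values and
    the bad-channel set.  ``apply_tddr=False`` skips motion repair for
    recordings known to be artifact-free; the robust re-weighting is a
    mild distortion of clean low-frequency signal, so skipping it is
    the higher-fidelity choice when there is nothing to repair.
    """
    quality = quality or QualityConfig()
    blc = blc or BeerLambertConfig(wavelengths=rec.wavelengths)

    od = intensity_to_od(rec)
    if apply_tddr:
        od = tddr_recording(od)
    od = short_channel_regress(od)
    sci = scalp_coupling_index(od, quality)
    bad = flag_bad_channels(sci, quality.sci_threshold)
    od.bad_channels |= bad
    od = interpolate_bad_channels(od, bad)
    if annotations:
        od.annotations = list(od.annotations) + list(annotations)
    hemo = od_to_hemo(od, blc)
    hemo = negative_correlation_enhance(hemo)
    hemo = bandpass(hemo, quality)
    report = {
        "sci": sci,
        "bad_channels": sorted(bad),
        "n_bad": len(bad),
        "n_long_retained": hemo.n_channels,
    }
    logger.info("preprocessing: %d bad channels of %d", len(bad), rec.n_channels)
    return hemo, report
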