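"""Raw two-wavelength fNIRS intensities -> clean, zero-mean ROI chromophore series.

The chain implemented here is the standard continuous-wave fNIRS pipeline:
optical density conversion, motion-artifact correction (moving-SD detection +
spline segment correction + wavelet outlier rejection), the modified
Beer-Lambert inversion with an age-dependent differential path length factor,
linear detrending/centering, spatial (global-mean) regression of systemic
physiology, and pooling of channels into seven reading-network regions of
interest per hemisphere.  No temporal band-pass filtering is applied at any
stage; frequency selection happens later, at the connectivity stage, by
band-averaging the spectral estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from scipy import interpolate, stats

__all__ = [
    "ROI_LABELS",
    "ROI_CHANNEL_COUNTS",
    "EXTINCTION_COEFFICIENTS",
    "RawIntensityRecording",
    "OpticalDensitySeries",
    "HemoglobinSeries",
    "ROITimeSeries",
    "dpf",
    "default_roi_map",
    "intensity_to_od",
    "correct_motion",
    "od_to_hemoglobin",
    "detrend_center",
    "remove_systemic",
    "pool_rois",
    "preprocess_recording",
]

#: Reading-network regions of interest, in canonical order.
ROI_LABELS = ("IFG", "STG", "MTG", "FFG", "SMG", "IPL", "ANG")

#: Channels pooled per ROI in the default montage (40 channels per hemisphere).
ROI_CHANNEL_COUNTS = {
    "IFG": 8,
    "STG": 6,
    "MTG": 8,
    "FFG": 6,
    "SMG": 4,
    "IPL": 4,
    "ANG": 4,
}

#: Decadic molar extinction coefficients [cm^-1 M^-1] for (HbO, HbR),
#: compiled values widely used in CW-fNIRS processing.  ``intensity_to_od``
#: uses the natural logarithm, so these are scaled by ln(10) when applied.
EXTINCTION_COEFFICIENTS = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}

LN10 = float(np.log(10.0))


def dpf(age_years: float) -> float:
    """Age-dependent differential path length factor, 4.99 + 0.067 * age**0.814.

    ``dpf(0) == 4.99`` exactly (the power term vanishes at age zero).
    """
    if age_years < 0:
        raise ValueError("age must be non-negative")
    return 4.99 + 0.067 * float(age_years) ** 0.814


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class RawIntensityRecording:
    """Two-wavelength light intensities, one row per (source, detector, wavelength).

    ``intensities`` has shape (n_measurements, n_times) and must be strictly
    positive.  Each source-detector pair must appear at exactly two
    wavelengths (760 and 850 nm).
    """

    intensities: np.ndarray
    wavelength: np.ndarray  # nm, per measurement row
    source: np.ndarray  # 1-based indices, per row
    detector: np.ndarray
    fs: float
    subject_age: float = 10.0
    source_detector_distance_cm: float = 3.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.source = np.asarray(self.source, dtype=int)
        self.detector = np.asarray(self.detector, dtype=int)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (measurements x time)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if np.any(self.intensities <= 0):
            row, t = np.argwhere(self.intensities <= 0)[0]
            raise ValueError(
                f"non-positive intensity at measurement {row}, sample {t}"
            )
        self._check_pairing()

    def _check_pairing(self) -> None:
        pairs: dict[tuple[int, int], set[float]] = {}
        for s, d, w in zip(self.source, self.detector, self.wavelength):
            pairs.setdefault((int(s), int(d)), set()).add(float(w))
        for pair, wls in pairs.items():
            if len(wls) != 2:
                raise ValueError(
                    f"source-detector pair {pair} has wavelengths {sorted(wls)}; "
                    "exactly two (760/850 nm) are required"
                )

    @property
    def n_times(self) -> int:
        return self.intensities.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def channel_pairs(self) -> list[tuple[int, int]]:
        """Unique (source, detector) pairs in first-appearance order."""
        seen: list[tuple[int, int]] = []
        for s, d in zip(self.source, self.detector):
            if (int(s), int(d)) not in seen:
                seen.append((int(s), int(d)))
        return seen


@dataclass
class OpticalDensitySeries:
    """Delta optical density per measurement row (dimensionless)."""

    delta_od: np.ndarray
    wavelength: np.ndarray
    source: np.ndarray
    detector: np.ndarray
    fs: float
    subject_age: float = 10.0
    source_detector_distance_cm: float = 3.0

    @property
    def n_times(self) -> int:
        return self.delta_od.shape[1]


@dataclass
class HemoglobinSeries:
    """Relative HbO/HbR concentration changes (uM) per source-detector channel."""

    hbo: np.ndarray  # (n_channels, n_times)
    hbr: np.ndarray
    source: np.ndarray  # per channel
    detector: np.ndarray
    fs: float
    dpf: float = 4.99
    source_detector_distance_cm: float = 3.0
    warnings_log: list = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_times(self) -> int:
        return self.hbo.shape[1]

    def select(self, chromophore: str) -> np.ndarray:
        if chromophore.lower() == "hbo":
            return self.hbo
        if chromophore.lower() == "hbr":
            return self.hbr
        raise ValueError(f"unknown chromophore {chromophore!r}")


@dataclass
class ROITimeSeries:
    """Zero-mean chromophore series pooled into the 7 reading-network ROIs."""

    series: np.ndarray  # (7, n_times)
    roi_labels: tuple = ROI_LABELS
    hemisphere: str = "left"
    chromophore: str = "HbO"
    fs: float = 7.8125
    n_channels_retained: int = 0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[0] != len(self.roi_labels):
            raise ValueError("series row count must match roi_labels")

    @property
    def n_times(self) -> int:
        return self.series.shape[1]


# ---------------------------------------------------------------------------
# Default channel -> ROI map
# ---------------------------------------------------------------------------


def default_roi_map(hemispheres=("left", "right")) -> pd.DataFrame:
    """Default channel->ROI assignment: 40 channels per hemisphere.

    Counts per ROI follow :data:`ROI_CHANNEL_COUNTS` (8 IFG, 6 STG, 8 MTG,
    6 FFG, 4 SMG, 4 IPL, 4 ANG).  Sources/detectors for the right hemisphere
    are offset by 100 so the two probes never collide.
    """
    rows = []
    for hemi in hemispheres:
        offset = 0 if hemi == "left" else 100
        src = 1
        for roi in ROI_LABELS:
            for k in range(ROI_CHANNEL_COUNTS[roi]):
                rows.append(
                    {
                        "source": offset + src,
                        "detector": offset + src + (k % 2),
                        "roi": roi,
                        "hemisphere": hemi,
                    }
                )
                src += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def intensity_to_od(
    recording: RawIntensityRecording, reference: str = "mean"
) -> OpticalDensitySeries:
    """Convert intensities to delta optical density, dOD(t) = ln(Phi_ref / Phi(t)).

    ``reference`` selects the per-row reference intensity: the temporal mean
    (default, robust to startup transients) or the first sample.
    """
    phi = recording.intensities
    if reference == "mean":
        ref = phi.mean(axis=1, keepdims=True)
    elif reference == "first":
        ref = phi[:, :1]
    else:
        raise ValueError("reference must be 'mean' or 'first'")
    od = np.log(ref / phi)
    return OpticalDensitySeries(
        delta_od=od,
        wavelength=recording.wavelength.copy(),
        source=recording.source.copy(),
        detector=recording.detector.copy(),
        fs=recording.fs,
        subject_age=recording.subject_age,
        source_detector_distance_cm=recording.source_detector_distance_cm,
    )


def _moving_std(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving standard deviation via cumulative sums (same length)."""
    n = x.shape[-1]
    half = window // 2
    pad = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(half, window - half)], mode="edge")
    c1 = np.cumsum(pad, axis=-1)
    c2 = np.cumsum(pad**2, axis=-1)
    s1 = c1[..., window:] - c1[..., :-window]
    s2 = c2[..., window:] - c2[..., :-window]
    s1, s2 = s1[..., :n], s2[..., :n]
    var = np.maximum(s2 / window - (s1 / window) ** 2, 0.0)
    return np.sqrt(var)


def _flag_segments(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    return list(zip(starts.tolist(), stops.tolist()))


def _spline_correct_channel(
    x: np.ndarray, segments: list[tuple[int, int]], smoothing: float
) -> np.ndarray:
    """Spline segment correction in the HomER tradition.

    Each flagged segment is refit with a near-interpolating smoothing spline
    (smoothing parameter p, default 0.99); the spline trend carries the
    artifact, the residual carries the physiology.  The residual is re-anchored
    to the preceding baseline level and everything after the segment is shifted
    to rejoin continuously, so both spikes and baseline shifts are removed.
    """
    y = x.copy()
    n = x.size
    for start, stop in segments:
        seg = y[start:stop].astype(float)
        m = seg.size
        if m >= 4:
            t = np.arange(m, dtype=float)
            s = (1.0 - smoothing) * m * float(seg.var())
            spl = interpolate.UnivariateSpline(t, seg, s=max(s, 0.0))
            trend = spl(t)
        else:
            trend = np.full(m, seg.mean())
        resid = seg - trend
        level = y[start - 1] if start > 0 else (y[stop] if stop < n else seg.mean())
        y[start:stop] = resid - resid[0] + level
        if stop < n:
            y[stop:] += y[stop - 1] - y[stop]
    return y


def _wavelet_correct_channel(
    x: np.ndarray, wavelet: str, level: int, alpha: float
) -> np.ndarray:
    """Zero detail coefficients in the outer ``alpha`` tail of a Gaussian fit.

    Per decomposition level the coefficient scale is estimated robustly
    (1.4826 * MAD); coefficients with |c| beyond the two-sided (1 - alpha)
    Gaussian quantile of that fit are treated as motion artifacts and zeroed.
    """
    n = x.size
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    level = min(level, max_level)
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    for i in range(1, len(coeffs)):
        c = coeffs[i]
        sigma = 1.4826 * np.median(np.abs(c - np.median(c)))
        if sigma <= 0:
            continue
        mask = np.abs(c - np.median(c)) > z * sigma
        c = c.copy()
        c[mask] = 0.0
        coeffs[i] = c
    rec = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return rec[:n]


def correct_motion(
    od: OpticalDensitySeries,
    window_s: float = 1.0,
    sd_thresh: float = 13.5,
    amp_thresh: float = 5.0,
    spline_smoothing: float = 0.99,
    wavelet_alpha: float = 0.1,
    wavelet: str = "db2",
    wavelet_level: int = 4,
) -> OpticalDensitySeries:
    """Motion-artifact correction: moving-SD + amplitude detection, spline
    segment correction, then wavelet coefficient rejection at tail
    probability ``wavelet_alpha``.

    Detection flags samples where the moving SD exceeds ``sd_thresh`` times the
    channel's robust SD or where the one-sample amplitude jump exceeds
    ``amp_thresh`` times that SD.  Artifact-free channels pass through the
    spline stage untouched.
    """
    x = od.delta_od
    n = x.shape[1]
    window = int(round(window_s * od.fs))
    if window < 2:
        raise ValueError("window_s * fs must span at least 2 samples")
    if window > n:
        raise ValueError("detection window is longer than the recording")

    out = np.empty_like(x)
    diffs = np.diff(x, axis=1, prepend=x[:, :1])
    msd = _moving_std(diffs, window)
    half = max(window // 2, 1)
    for ch in range(x.shape[0]):
        xc = x[ch]
        dc = diffs[ch]
        # detection runs on first differences: haemodynamics are smooth, so
        # spikes and baseline shifts stand out against the derivative scale
        scale = 1.4826 * np.median(np.abs(dc - np.median(dc)))
        if scale <= 0:
            scale = dc.std() or 1.0
        flags = msd[ch] > sd_thresh * scale
        flags |= np.abs(dc) > amp_thresh * scale
        if flags.any():  # dilate so artifact tails are inside the segments
            idx = np.flatnonzero(flags)
            dilated = np.zeros(n, dtype=bool)
            for i in idx:
                dilated[max(0, i - half) : min(n, i + half + 1)] = True
            flags = dilated
        segments = _flag_segments(flags)
        yc = _spline_correct_channel(xc, segments, spline_smoothing) if segments else xc
        out[ch] = _wavelet_correct_channel(yc, wavelet, wavelet_level, wavelet_alpha)
    return replace(od, delta_od=out)


def extinction_matrix(
    wavelengths=(760.0, 850.0), table: dict | None = None
) -> np.ndarray:
    """2x2 matrix E (per-uM, natural-log units): rows = wavelengths, cols = (HbO, HbR)."""
    table = EXTINCTION_COEFFICIENTS if table is None else table
    rows = []
    for wl in wavelengths:
        if wl not in table:
            raise KeyError(f"no extinction coefficients for {wl} nm")
        e_hbo, e_hbr = table[wl]
        rows.append([e_hbo * LN10 * 1e-6, e_hbr * LN10 * 1e-6])
    return np.asarray(rows)


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    age_years: float | None = None,
    distance_cm: float | None = None,
    extinction_table: dict | None = None,
) -> HemoglobinSeries:
    """Modified Beer-Lambert inversion: per source-detector pair solve the 2x2
    system dOD_lambda = E[lambda, :] . [HbO, HbR] * distance * DPF(age).

    Concentrations come out in uM because the extinction matrix is expressed
    per uM.  ``DPF(0) == 4.99`` by construction of :func:`dpf`.
    """
    age = od.subject_age if age_years is None else age_years
    dist = od.source_detector_distance_cm if distance_cm is None else distance_cm
    pathlen = dist * dpf(age)

    pairs: dict[tuple[int, int], dict[float, int]] = {}
    for row, (s, d, wl) in enumerate(zip(od.source, od.detector, od.wavelength)):
        pairs.setdefault((int(s), int(d)), {})[float(wl)] = row

    sources, detectors, hbo_rows, hbr_rows = [], [], [], []
    for (s, d), wl_rows in pairs.items():
        wls = sorted(wl_rows)
        if len(wls) != 2:
            raise ValueError(f"pair ({s},{d}) is missing a wavelength partner")
        E = extinction_matrix(wls, extinction_table)
        if abs(np.linalg.det(E)) < 1e-18:
            raise np.linalg.LinAlgError("extinction matrix is singular")
        od_stack = np.vstack([od.delta_od[wl_rows[wl]] for wl in wls])
        conc = np.linalg.solve(E * pathlen, od_stack)
        sources.append(s)
        detectors.append(d)
        hbo_rows.append(conc[0])
        hbr_rows.append(conc[1])

    return HemoglobinSeries(
        hbo=np.vstack(hbo_rows),
        hbr=np.vstack(hbr_rows),
        source=np.asarray(sources),
        detector=np.asarray(detectors),
        fs=od.fs,
        dpf=dpf(age),
        source_detector_distance_cm=dist,
    )


def _detrend_matrix(x: np.ndarray) -> tuple[np.ndarray, list[int]]:
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples to detrend")
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    out = x - (design @ beta).T
    constant = [ch for ch in range(x.shape[0]) if np.ptp(x[ch]) == 0.0]
    for ch in constant:
        out[ch] = 0.0
    return out, constant


def detrend_center(hb: HemoglobinSeries) -> HemoglobinSeries:
    """Remove the per-channel best-fit line and center to zero mean.

    Constant channels are mapped to zeros and recorded in ``warnings_log``.
    No band-pass filtering is applied here or anywhere else in preprocessing.
    """
    hbo, const_o = _detrend_matrix(hb.hbo)
    hbr, const_r = _detrend_matrix(hb.hbr)
    log = list(hb.warnings_log)
    for ch in const_o:
        log.append(f"hbo channel {ch} constant; zeroed")
    for ch in const_r:
        log.append(f"hbr channel {ch} constant; zeroed")
    if const_o or const_r:
        warnings.warn("constant channel(s) zeroed during detrending", stacklevel=2)
    return replace(hb, hbo=hbo, hbr=hbr, warnings_log=log)


def _regress_out_global(x: np.ndarray, exclude: list | None = None) -> np.ndarray:
    """Regress the cross-channel mean out of every channel.

    ``exclude`` maps each channel index to the set of channel indices left out
    of its regressor (its own region), so local activity does not contaminate
    the systemic estimate for the channels that carry it.
    """
    n_ch = x.shape[0]
    total = x.sum(axis=0)
    out = np.empty_like(x)
    for ch in range(n_ch):
        drop = exclude[ch] if exclude is not None else [ch]
        g = (total - x[drop].sum(axis=0)) / max(n_ch - len(drop), 1)
        denom = float(g @ g)
        if denom == 0.0:
            out[ch] = x[ch]
            continue
        beta = float(x[ch] @ g) / denom
        out[ch] = x[ch] - beta * g
    return out


def remove_systemic(
    hb: HemoglobinSeries, roi_map: pd.DataFrame | None = None
) -> HemoglobinSeries:
    """Spatial-domain regression filtering of non-neural physiology.

    The cross-channel mean (the spatially global component: Mayer waves,
    respiration, scalp blood flow) is regressed out of every channel per
    chromophore; residuals are orthogonal to the removed regressor.  Each
    channel's regressor excludes the channel itself — and, when ``roi_map``
    is given, all channels of its own region — so regional activity is not
    subtracted from the very channels that measure it.  With a single channel
    this is a no-op (warned), since no spatial information exists to separate
    systemic from neural signal.
    """
    if hb.n_channels < 2:
        warnings.warn("single channel: systemic removal skipped", stacklevel=2)
        return replace(hb, warnings_log=list(hb.warnings_log) + ["systemic removal skipped"])
    exclude = None
    if roi_map is not None:
        index = {
            (int(s), int(d)): k for k, (s, d) in enumerate(zip(hb.source, hb.detector))
        }
        roi_of: dict[int, tuple] = {}
        for row in roi_map.itertuples():
            key = (int(row.source), int(row.detector))
            if key in index:
                roi_of[index[key]] = (row.hemisphere, row.roi)
        members: dict[tuple, list] = {}
        for ch, roi in roi_of.items():
            members.setdefault(roi, []).append(ch)
        exclude = [
            members.get(roi_of.get(ch), [ch]) if ch in roi_of else [ch]
            for ch in range(hb.n_channels)
        ]
    return replace(
        hb,
        hbo=_regress_out_global(hb.hbo, exclude),
        hbr=_regress_out_global(hb.hbr, exclude),
    )


def pool_rois(
    hb: HemoglobinSeries,
    roi_map: pd.DataFrame,
    hemisphere: str = "left",
    chromophore: str = "HbO",
) -> ROITimeSeries:
    """Average member channels into the 7 ROIs for one hemisphere.

    ``roi_map`` needs columns source, detector, roi, hemisphere.  Channels not
    in the map are dropped; an ROI with no mapped channel present in the data
    is an error.
    """
    sel = roi_map[roi_map["hemisphere"] == hemisphere]
    data = hb.select(chromophore)
    index = {(int(s), int(d)): i for i, (s, d) in enumerate(zip(hb.source, hb.detector))}
    series = np.zeros((len(ROI_LABELS), hb.n_times))
    retained = 0
    for r, roi in enumerate(ROI_LABELS):
        members = sel[sel["roi"] == roi]
        rows = [
            index[(int(m.source), int(m.detector))]
            for m in members.itertuples()
            if (int(m.source), int(m.detector)) in index
        ]
        if not rows:
            raise ValueError(f"ROI {roi} ({hemisphere}) has no mapped channels in the data")
        series[r] = data[rows].mean(axis=0)
        retained += len(rows)
    return ROITimeSeries(
        series=series,
        hemisphere=hemisphere,
        chromophore=chromophore,
        fs=hb.fs,
        n_channels_retained=retained,
    )


def preprocess_recording(
    recording: RawIntensityRecording,
    roi_map: pd.DataFrame | None = None,
    chromophore: str = "HbO",
    motion_params: dict | None = None,
    reference: str = "mean",
) -> dict[str, ROITimeSeries]:
    """Full preprocessing chain; returns one ROITimeSeries per hemisphere present."""
    roi_map = default_roi_map() if roi_map is None else roi_map
    od = intensity_to_od(recording, reference=reference)
    od = correct_motion(od, **(motion_params or {}))
    hb = od_to_hemoglobin(od)
    hb = detrend_center(hb)
    hb = remove_systemic(hb, roi_map=roi_map)
    present = {(int(s), int(d)) for s, d in zip(hb.source, hb.detector)}
    out = {}
    for hemi in sorted(roi_map["hemisphere"].unique()):
        sel = roi_map[roi_map["hemisphere"] == hemi]
        if not any(
            (int(r.source), int(r.detector)) in present for r in sel.itertuples()
        ):
            continue  # probe not present in this recording
        out[hemi] = pool_rois(hb, roi_map, hemisphere=hemi, chromophore=chromophore)
        # pooling of centered channels keeps means at zero; re-center defensively
        out[hemi].series -= out[hemi].series.mean(axis=1, keepdims=True)
    return out
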