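"""Cleaning chain from raw recordings to analysis-ready task epochs.

The canonical stage order is::

    resample -> highpass -> line-noise removal -> bad-channel detection /
    spherical-spline interpolation -> average reference -> epoch ->
    artifact subspace reconstruction -> average reference -> surface
    Laplacian

as run by :func:`run_pipeline`, which records each stage in a
:class:`~skillstate.io.RunManifest` so the order can be audited.
All stages are shape-preserving in channels and never introduce NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.signal

from .io import Montage, Recording, RunManifest, ValidationError
from .spline import interpolation_matrix, laplacian_matrix

__all__ = [
    "PreprocessConfig",
    "EpochSet",
    "resample",
    "highpass",
    "remove_line_noise",
    "detect_bad_channels",
    "interpolate_channels",
    "subject_admissible",
    "average_reference",
    "asr_calibrate",
    "asr_clean",
    "surface_laplacian",
    "extract_task_epochs",
    "run_pipeline",
    "PIPELINE_ORDER",
]

PIPELINE_ORDER = [
    "resample",
    "highpass",
    "remove_line_noise",
    "detect_bad_channels",
    "interpolate_channels",
    "average_reference",
    "extract_task_epochs",
    "asr_clean",
    "average_reference",
    "surface_laplacian",
]


@dataclass
class PreprocessConfig:
    """Tunables of the cleaning chain (defaults follow common toolbox
    settings for this kind of data: 250 Hz working rate, 1 Hz high-pass,
    ASR cutoff 20, subjects excluded at >= 5 bad channels)."""

    target_fs: float = 250.0
    hp_cutoff: float = 1.0
    hp_transition: float = 1.0
    line_freq: float = 60.0
    asr_cutoff: float = 20.0
    asr_window_s: float = 0.5
    bad_channel_corr_threshold: float = 0.45
    flatline_s: float = 5.0
    max_bad_channels: int = 5  # exclusive bound: >=5 flags -> excluded
    epoch_onset_s: float = 0.0
    epoch_duration_s: float = 10.0
    trigger_label: str = "start"
    calibration_s: float = 60.0  # rest-tail length used to calibrate ASR
    head_radius_m: float = 0.09


@dataclass
class EpochSet:
    """Equal-shape task epochs with cohort bookkeeping."""

    epochs: np.ndarray  # (n_epochs, n_samples, n_channels)
    fs: float
    subject: str | None = None
    trial: int | None = None
    group: str | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, float)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be (n_epochs, samples, channels)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def is_average_referenced(self, tol: float = 1e-9) -> bool:
        if self.epochs.size == 0:
            return True
        scale = max(1.0, float(np.abs(self.epochs).max()))
        return bool(
            np.abs(self.epochs.mean(axis=2)).max() <= tol * scale + tol
        )


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling; events rescale with round-half-even."""
    if target_fs > rec.fs:
        raise ValidationError("upsampling not supported")
    if target_fs == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = scipy.signal.resample_poly(rec.data, up, down, axis=0)
    ratio = target_fs / rec.fs
    n_new = data.shape[0]
    events = [
        (min(n_new - 1, int(np.round(s * ratio))), lbl) for s, lbl in rec.events
    ]
    return Recording(data, target_fs, rec.channel_names, events, rec.reference)


def _hp_taps(fs: float, cutoff: float, transition: float) -> np.ndarray:
    numtaps = int(np.ceil(3.3 / (transition / fs)))
    numtaps += 1 - numtaps % 2  # odd length -> symmetric, integer delay
    taps = scipy.signal.firwin(
        numtaps, cutoff, width=transition, fs=fs, pass_zero=False
    )
    return taps - taps.sum() / numtaps  # exact null at DC


def highpass(rec: Recording, cutoff: float, transition: float = 1.0) -> Recording:
    """Zero-phase FIR high-pass (Hamming design, linear phase applied
    symmetrically so there is no group delay)."""
    if cutoff >= rec.fs / 2:
        raise ValidationError("cutoff must be below Nyquist")
    taps = _hp_taps(rec.fs, cutoff, transition)
    pad = len(taps) // 2
    padded = np.pad(rec.data, ((pad, pad), (0, 0)), mode="reflect")
    out = scipy.signal.fftconvolve(padded, taps[:, None], mode="same", axes=0)
    out = out[pad:-pad]
    return rec.copy_with(data=out)


def remove_line_noise(
    rec: Recording,
    line_freq: float,
    n_harmonics: int = 2,
    window_s: float = 4.0,
) -> Recording:
    """Narrowband mains suppression by sliding-window sinusoid regression.

    In each Hann-weighted window (50% overlap) a sine/cosine pair at the
    line frequency and its harmonics is regressed out of every channel.
    Only ~2 degrees of freedom per window and harmonic are removed, so
    broadband content passes essentially unchanged.
    """
    if line_freq >= rec.fs / 2:
        raise ValidationError("line frequency at or above Nyquist")
    freqs = [line_freq * (h + 1) for h in range(n_harmonics)]
    freqs = [f for f in freqs if f < rec.fs / 2]

    n = rec.n_samples
    win = int(round(window_s * rec.fs))
    win = min(win, n)
    hop = max(1, win // 2)
    t = np.arange(win) / rec.fs
    D = np.column_stack(
        [fn(2 * np.pi * f * t) for f in freqs for fn in (np.sin, np.cos)]
    )
    P = D @ np.linalg.pinv(D)  # projection onto the line-noise subspace
    w = np.hanning(win)

    num = np.zeros_like(rec.data)
    den = np.zeros(n)
    starts = list(range(0, max(1, n - win + 1), hop))
    if starts[-1] + win < n:
        starts.append(n - win)
    for s in starts:
        seg = rec.data[s : s + win]
        cleaned = seg - P @ seg
        num[s : s + win] += w[:, None] * cleaned
        den[s : s + win] += w
    ok = den > 1e-8
    out = rec.data.copy()
    out[ok] = num[ok] / den[ok, None]
    return rec.copy_with(data=out)


def detect_bad_channels(
    rec: Recording,
    montage: Montage,
    corr_threshold: float = 0.45,
    flatline_s: float = 5.0,
    window_s: float = 1.0,
) -> set[int]:
    """Flag flatline channels and channels that no longer resemble their
    spherical-spline estimate from the remaining electrodes.

    A channel is flagged when its best windowed correlation with the
    leave-one-out spline estimate falls below ``corr_threshold``:
    peripheral electrodes correlate only moderately on average, but a
    genuinely connected channel has at least some windows of high
    agreement, while a disconnected one has none (typically < 0.1 versus
    > 0.5 for connected channels, hence the 0.45 default for this
    statistic).
    """
    if rec.duration < 10.0:
        raise ValidationError("need >= 10 s of data for bad-channel detection")
    pos = montage.subset(rec.channel_names).positions
    n, n_ch = rec.data.shape
    flagged: set[int] = set()

    # flatline: longest run of near-zero first differences
    d = np.abs(np.diff(rec.data, axis=0)) < 1e-10
    max_run_needed = int(flatline_s * rec.fs)
    for c in range(n_ch):
        runs = _longest_true_run(d[:, c])
        if runs >= max_run_needed:
            flagged.add(c)

    win = int(round(window_s * rec.fs))
    n_win = n // win
    X = rec.data[: n_win * win].reshape(n_win, win, n_ch)
    for c in range(n_ch):
        others = [i for i in range(n_ch) if i != c]
        W = interpolation_matrix(pos[others], pos[c][None, :])
        est = rec.data[: n_win * win, others] @ W[0]
        est_w = est.reshape(n_win, win)
        x_w = X[:, :, c]
        corr = _rowwise_corr(x_w, est_w)
        if corr.max() < corr_threshold:
            flagged.add(c)
    return flagged


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return int((edges[1::2] - edges[::2]).max())


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    denom[denom == 0] = np.inf
    return (a * b).sum(axis=1) / denom


def interpolate_channels(
    rec: Recording, montage: Montage, flagged: set[int] | list[int]
) -> Recording:
    """Replace flagged channels by spherical-spline interpolation (order 4,
    ridge 1e-5) from the good channels."""
    flagged = sorted(set(int(c) for c in flagged))
    n_ch = rec.n_channels
    if len(flagged) >= n_ch:
        raise ValidationError("cannot interpolate: all channels flagged")
    if not flagged:
        return rec.copy_with(data=rec.data.copy())
    pos = montage.subset(rec.channel_names).positions
    good = [c for c in range(n_ch) if c not in flagged]
    W = interpolation_matrix(pos[good], pos[flagged])
    data = rec.data.copy()
    data[:, flagged] = rec.data[:, good] @ W.T
    return rec.copy_with(data=data)


def subject_admissible(flagged, max_bad_channels: int = 5) -> bool:
    """Subjects with >= ``max_bad_channels`` flagged channels are excluded."""
    return len(flagged) < max_bad_channels


def average_reference(rec: Recording) -> Recording:
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.copy_with(data=out, reference="common-average")


# --------------------------------------------------------------------------
# artifact subspace reconstruction (offline, Euclidean)
# --------------------------------------------------------------------------

@dataclass
class ASRCalibration:
    sqrt_cov: np.ndarray      # principal square root of calibration covariance
    thresholds: np.ndarray    # per-component RMS ceilings, calibration frame
    mixing: np.ndarray        # calibration eigenvectors (columns)


def asr_calibrate(
    calibration: Recording | np.ndarray,
    cutoff: float = 20.0,
    window_s: float = 0.5,
    fs: float | None = None,
) -> ASRCalibration:
    """Estimate the clean-subspace statistics from low-artifact data.

    Component-wise windowed RMS distributions are summarized robustly
    (median and scaled MAD); the rejection ceiling for component j is
    ``median_j + cutoff * 1.4826 MAD_j``.
    """
    if isinstance(calibration, Recording):
        X = calibration.data
        fs = calibration.fs
    else:
        X = np.asarray(calibration, float)
        if fs is None:
            raise ValidationError("fs required with array calibration data")
    win = int(round(window_s * fs))
    if X.shape[0] < win:
        raise ValidationError("calibration shorter than the ASR window")
    X = X - X.mean(axis=0)
    M = (X.T @ X) / X.shape[0]
    evals, evecs = np.linalg.eigh(M)
    evals = np.clip(evals, 1e-15, None)
    sqrt_cov = (evecs * np.sqrt(evals)) @ evecs.T

    Y = X @ evecs
    n_win = Y.shape[0] // win
    rms = np.sqrt(
        (Y[: n_win * win].reshape(n_win, win, -1) ** 2).mean(axis=1)
    )
    mu = np.median(rms, axis=0)
    sig = 1.4826 * np.median(np.abs(rms - mu), axis=0)
    thresholds = mu + cutoff * sig
    return ASRCalibration(sqrt_cov, thresholds, evecs)


def asr_clean(
    rec: Recording,
    calibration: Recording | ASRCalibration,
    cutoff: float = 20.0,
    window_s: float = 0.5,
) -> Recording:
    """Reconstruct artifact components from the calibration subspace.

    Sliding 50%-overlap windows are eigendecomposed; components whose
    variance exceeds the calibration ceiling along their direction are
    rejected and the window is reprojected through the retained subspace
    (raised-cosine blending across windows).  With an infinite cutoff the
    data pass through untouched.
    """
    if np.isinf(cutoff):
        return rec.copy_with(data=rec.data.copy())
    cal = (
        calibration
        if isinstance(calibration, ASRCalibration)
        else asr_calibrate(calibration, cutoff, window_s)
    )
    X = rec.data
    n, n_ch = X.shape
    win = min(int(round(window_s * rec.fs)), n)
    hop = max(1, win // 2)
    T = np.diag(cal.thresholds) @ cal.mixing.T  # threshold operator

    num = np.zeros_like(X)
    den = np.zeros(n)
    w = np.hanning(win) + 1e-3
    starts = list(range(0, max(1, n - win + 1), hop))
    if starts[-1] + win < n:
        starts.append(n - win)
    for s in starts:
        seg = X[s : s + win]
        C = (seg.T @ seg) / seg.shape[0]
        D, V = np.linalg.eigh(C)
        limits = ((T @ V) ** 2).sum(axis=0)
        keep = D < limits
        if keep.all():
            cleaned = seg
        elif not keep.any():
            cleaned = np.zeros_like(seg)
        else:
            A = V.T @ cal.sqrt_cov
            A_trunc = A * keep[:, None]
            R = cal.sqrt_cov @ np.linalg.pinv(A_trunc) @ V.T
            cleaned = seg @ R.T
        num[s : s + win] += w[:, None] * cleaned
        den[s : s + win] += w
    out = num / den[:, None]
    return rec.copy_with(data=out)


def surface_laplacian(
    rec: Recording, montage: Montage, head_radius_m: float = 0.09
) -> Recording:
    """Spherical-spline surface Laplacian (current source density).

    Output units are microvolts per square metre of scalp for the default
    9 cm head radius.  A spatially constant field maps to ~0 and the
    operator is linear in the input.
    """
    pos = montage.subset(rec.channel_names).positions
    L = laplacian_matrix(pos, head_radius_m=head_radius_m)
    return rec.copy_with(data=rec.data @ L.T)


def extract_task_epochs(
    rec: Recording,
    trigger_label: str = "start",
    onset_s: float = 0.0,
    duration_s: float = 10.0,
) -> EpochSet:
    """One epoch per trigger, ``duration_s`` long starting at
    ``trigger + onset_s`` (onset may be negative)."""
    trig = rec.event_samples(trigger_label)
    if not trig:
        raise ValidationError(f"no {trigger_label!r} trigger in recording")
    n_samp = int(round(duration_s * rec.fs))
    offset = int(round(onset_s * rec.fs))
    epochs = []
    for s in trig:
        a = s + offset
        b = a + n_samp
        if a < 0 or b > rec.n_samples:
            raise ValidationError(
                f"epoch [{a}, {b}) exceeds recording of {rec.n_samples} samples"
            )
        epochs.append(rec.data[a:b])
    return EpochSet(np.array(epochs), rec.fs, channel_names=rec.channel_names)


# --------------------------------------------------------------------------
# pipeline runner
# --------------------------------------------------------------------------

def run_pipeline(
    rec: Recording,
    montage: Montage,
    cfg: PreprocessConfig | None = None,
    manifest: RunManifest | None = None,
) -> tuple[EpochSet | None, dict]:
    """Run the full cleaning chain on one recording.

    Returns the cleaned epochs (None when the subject is inadmissible) and
    a QC dict.  ASR is calibrated on the final ``calibration_s`` seconds
    of the recording (the post-task rest period).
    """
    cfg = cfg or PreprocessConfig()
    manifest = manifest if manifest is not None else RunManifest()

    rec = resample(rec, cfg.target_fs)
    manifest.log("resample", target_fs=cfg.target_fs)
    rec = highpass(rec, cfg.hp_cutoff, cfg.hp_transition)
    manifest.log("highpass", cutoff=cfg.hp_cutoff)
    rec = remove_line_noise(rec, cfg.line_freq)
    manifest.log("remove_line_noise", line_freq=cfg.line_freq)
    flagged = detect_bad_channels(
        rec, montage, cfg.bad_channel_corr_threshold, cfg.flatline_s
    )
    manifest.log("detect_bad_channels", flagged=sorted(flagged))
    qc = {
        "flagged_channels": sorted(flagged),
        "admissible": subject_admissible(flagged, cfg.max_bad_channels),
    }
    if not qc["admissible"]:
        return None, qc
    rec = interpolate_channels(rec, montage, flagged)
    manifest.log("interpolate_channels", n=len(flagged))
    rec = average_reference(rec)
    manifest.log("average_reference")

    epochs = extract_task_epochs(
        rec, cfg.trigger_label, cfg.epoch_onset_s, cfg.epoch_duration_s
    )
    manifest.log(
        "extract_task_epochs",
        onset_s=cfg.epoch_onset_s,
        duration_s=cfg.epoch_duration_s,
    )

    calib_n = int(round(cfg.calibration_s * rec.fs))
    calib = Recording(
        rec.data[-calib_n:], rec.fs, rec.channel_names, [], rec.reference
    )
    cal = asr_calibrate(calib, cfg.asr_cutoff, cfg.asr_window_s)
    cleaned = []
    for ep in epochs.epochs:
        tmp = Recording(ep, rec.fs, rec.channel_names, [], rec.reference)
        tmp = asr_clean(tmp, cal, cfg.asr_cutoff, cfg.asr_window_s)
        manifest.log("asr_clean", cutoff=cfg.asr_cutoff)
        tmp = average_reference(tmp)
        manifest.log("average_reference")
        tmp = surface_laplacian(tmp, montage, cfg.head_radius_m)
        manifest.log("surface_laplacian")
        cleaned.append(tmp.data)
    out = EpochSet(
        np.array(cleaned).reshape(epochs.n_epochs, -1, rec.n_channels),
        rec.fs,
        channel_names=rec.channel_names,
    )
    return out, qc
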