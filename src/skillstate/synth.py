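"""Synthetic two-group EEG with planted topographic structure.

Emulates the study protocol that motivates the package: 32-channel 500 Hz
scalp EEG, repeated trials of a 3-minute bimanual task preceded by a
'start' trigger and followed by a 2-minute rest, recorded from two groups
("expert", "novice").  The scalp signal is a piecewise-constant sequence of
quasi-stable prototype topographies (microstates, dwell 50-150 ms) whose
occurrence probabilities differ between groups during the task, riding on
1/f background noise plus mains interference.  This gives every downstream
stage — preprocessing, microstate clustering, CSP, tensorization, and the
CNN — a ground truth to recover.

What this generator does NOT emulate: biophysical volume conduction from
cortical sources, ocular/muscle artifact morphology (only amplitude bursts
for exercising artifact subspace reconstruction), electrode drift, or
inter-subject anatomical variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Montage, Recording, ValidationError, default_montage, write_recording

__all__ = [
    "SimulationSpec",
    "make_prototype_bank",
    "special_prototype_indices",
    "simulate_subject",
    "simulate_cohort",
    "make_planted_tensor_dataset",
]


def special_prototype_indices(K: int) -> tuple[int, int]:
    """(expert-dominant, novice-dominant) prototype indices in the bank.

    For K >= 4 these sit at 0-based indices 3 and 1 (the left-posterior and
    right-frontal/left-posterior maps, echoing the field's microstates 4
    and 2); for smaller banks they occupy the first two slots.
    """
    if K >= 4:
        return 3, 1
    return 0, 1


def make_prototype_bank(
    montage: Montage, K: int, seed: int = 0
) -> np.ndarray:
    """K unit-norm, zero-mean scalp topographies with pairwise |r| < 0.7.

    The bank always contains a left-posterior-weighted map (expert-like)
    and a right-frontal-positive / left-posterior-negative dipole
    (novice-like); see :func:`special_prototype_indices`.  Remaining maps
    are random smooth combinations of low-order spatial harmonics.
    """
    n_ch = len(montage)
    if K > n_ch:
        raise ValidationError(f"K={K} exceeds {n_ch} channels")
    if K < 1:
        raise ValidationError("K must be >= 1")
    pos = montage.positions
    x, y, z = pos.T  # +x right, +y anterior, +z superior (head frame)

    def norm(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ValidationError("degenerate prototype")
        return v / n

    def bump(direction, kappa=8.0):
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        return np.exp(kappa * (pos @ u - 1.0))

    # designated maps
    left_posterior = norm(bump([-0.6, -0.6, 0.5]))          # "microstate 4"
    rf_lp_dipole = norm(x + y)                              # "microstate 2"
    occipital = norm(bump([0.0, -0.85, 0.3]))               # visual, "ms 1"
    frontal_midline = norm(bump([0.0, 0.8, 0.45]))

    basis = np.column_stack(
        [x, y, z, x * y, x * z, y * z, x**2 - y**2, 3 * z**2 - 1]
    )
    rng = np.random.default_rng(seed)

    slots: dict[int, np.ndarray] = {}
    e_idx, n_idx = special_prototype_indices(K)
    slots[e_idx] = left_posterior
    slots[n_idx] = rf_lp_dipole
    if K >= 4:
        if 0 not in slots:
            slots[0] = occipital
        if 2 not in slots:
            slots[2] = frontal_midline
    if K == 1:
        return left_posterior[None, :]

    bank = [None] * K
    for i, v in slots.items():
        if i < K:
            bank[i] = v

    def acceptable(cand):
        return all(
            b is None or abs(float(cand @ b)) < 0.7 for b in bank
        )

    for i in range(K):
        if bank[i] is not None:
            continue
        for _ in range(500):
            cand = norm(basis @ rng.standard_normal(basis.shape[1]))
            if acceptable(cand):
                bank[i] = cand
                break
        else:  # deterministically decorrelate against the existing maps
            others = np.array([b for b in bank if b is not None])
            cand = norm(basis @ rng.standard_normal(basis.shape[1]))
            cand = norm(cand - others.T @ (others @ cand))
            bank[i] = cand
    return np.array(bank)


@dataclass
class SimulationSpec:
    """Study-protocol parameters for the synthetic cohort.

    Defaults mirror the emulated study: 8 experts and 13 novices, three
    trials each, 32 channels at 500 Hz, a 180 s task preceded by a 'start'
    trigger and followed by 120 s of rest.  ``snr_db`` is defined on
    average-referenced broadband power (0 dB keeps classification
    nontrivial but achievable); mains interference defaults to 60 Hz.
    """

    n_experts: int = 8
    n_novices: int = 13
    trials_per_subject: int = 3
    fs: float = 500.0
    task_s: float = 180.0
    rest_s: float = 120.0
    pre_trigger_s: float = 5.0
    montage: Montage = field(default_factory=default_montage)
    prototype_bank: np.ndarray | None = None  # (K, n_channels)
    group_prototype_weights: dict[str, np.ndarray] | None = None
    snr_db: float = 0.0
    line_freq: float = 60.0
    bad_channel_prob: float = 0.0
    dwell_ms: tuple[float, float] = (50.0, 150.0)
    dominance: float = 0.6  # task-time weight of the group's own prototype
    burst_prob_per_min: float = 0.0  # high-amplitude artifact bursts (for ASR)
    trigger_label: str = "start"
    confined_state: int | None = None   # group difference confined to one state
    confined_delta: float = 0.2         # topographic perturbation strength
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task_s <= 0 or self.rest_s <= 0:
            raise ValidationError("task_s and rest_s must be positive")
        if self.prototype_bank is None:
            self.prototype_bank = make_prototype_bank(self.montage, 6, self.seed)
        self.prototype_bank = np.asarray(self.prototype_bank, float)
        K = self.K
        if K < 2:
            raise ValidationError("prototype bank needs K >= 2")
        if self.group_prototype_weights is None:
            e_idx, n_idx = special_prototype_indices(K)
            self.group_prototype_weights = {
                "expert": _dominant_weights(K, e_idx, self.dominance),
                "novice": _dominant_weights(K, n_idx, self.dominance),
            }
        for g, w in self.group_prototype_weights.items():
            w = np.asarray(w, float)
            if w.shape != (K,) or abs(w.sum() - 1) > 1e-9 or (w < 0).any():
                raise ValidationError(f"weights for {g!r} not a length-{K} pmf")
            self.group_prototype_weights[g] = w
        # confined-difference regime: identical occurrence statistics for
        # both groups; the two groups express slightly different
        # topographic variants of one state only
        self.confined_variants: dict[str, np.ndarray] | None = None
        if self.confined_state is not None:
            s = int(self.confined_state)
            if not 0 <= s < K:
                raise ValidationError("confined_state outside the bank")
            w_eq = _dominant_weights(K, s, 0.3)
            self.group_prototype_weights = {
                "expert": w_eq, "novice": w_eq.copy()
            }
            p = self.prototype_bank[s]
            rng = np.random.default_rng([self.seed, 777])
            d = make_prototype_bank(self.montage, 2, int(rng.integers(2**31)))[1]
            d = d - (d @ p) * p
            d /= np.linalg.norm(d)

            def variant(sign: float) -> np.ndarray:
                v = p + sign * self.confined_delta * d
                v = v - v.mean()
                return v / np.linalg.norm(v)

            self.confined_variants = {
                "expert": variant(+1.0), "novice": variant(-1.0)
            }

    @property
    def K(self) -> int:
        return self.prototype_bank.shape[0]

    @property
    def trial_duration_s(self) -> float:
        return self.pre_trigger_s + self.task_s + self.rest_s


def _dominant_weights(K: int, idx: int, dominance: float) -> np.ndarray:
    w = np.full(K, (1 - dominance) / (K - 1))
    w[idx] = dominance
    return w


def _one_over_f_noise(rng: np.random.Generator, n: int, n_ch: int, fs: float
                      ) -> np.ndarray:
    """Channel-independent 1/f (power) noise, unit variance per channel."""
    white = rng.standard_normal((n, n_ch))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    noise = np.fft.irfft(spec * shape[:, None], n=n, axis=0)
    return noise / noise.std(axis=0, keepdims=True)


def simulate_subject(
    spec: SimulationSpec,
    group: str,
    subject_id: int,
    trial_id: int,
) -> Recording:
    """One trial recording: pre-trigger rest, task, post-task rest.

    The 'start' event marks task onset.  During the task the microstate
    sequence draws prototypes from the group's weight vector; during rest
    segments all prototypes are equiprobable.  Deterministic for a fixed
    (spec.seed, group, subject, trial).
    """
    if group not in spec.group_prototype_weights:
        raise ValidationError(f"unknown group {group!r}")
    fs = spec.fs
    n = int(round(spec.trial_duration_s * fs))
    n_ch = spec.prototype_bank.shape[1]
    rng = np.random.default_rng(
        [spec.seed, 1 if group == "expert" else 2, subject_id, trial_id]
    )

    task_start = int(round(spec.pre_trigger_s * fs))
    task_end = int(round((spec.pre_trigger_s + spec.task_s) * fs))

    # piecewise-constant microstate sequence
    signal = np.empty((n, n_ch))
    lo, hi = spec.dwell_ms
    w_task = spec.group_prototype_weights[group]
    w_rest = np.full(spec.K, 1.0 / spec.K)
    t = 0
    while t < n:
        dwell = max(1, int(round(rng.uniform(lo, hi) * 1e-3 * fs)))
        in_task = task_start <= t < task_end
        proto = rng.choice(spec.K, p=w_task if in_task else w_rest)
        amp = rng.lognormal(mean=0.0, sigma=0.35)
        sign = rng.choice([-1.0, 1.0])
        seg = slice(t, min(t + dwell, n))
        topo = spec.prototype_bank[proto]
        if (
            spec.confined_variants is not None
            and in_task
            and proto == spec.confined_state
        ):
            topo = spec.confined_variants[group]
        signal[seg] = (amp * sign) * topo
        t += dwell

    # smooth strictly-positive GFP envelope (slow amplitude modulation)
    env = _one_over_f_noise(rng, n, 1, fs)[:, 0]
    env = 1.0 + 0.3 * env
    np.clip(env, 0.2, None, out=env)
    scale_uv = 10.0  # microvolt scale of the prototype signal
    signal *= (scale_uv * env)[:, None]

    data = signal.copy()
    if math.isfinite(spec.snr_db):
        p_signal = float(np.mean(signal**2))
        p_noise = p_signal / 10 ** (spec.snr_db / 10)
        # background noise is spatially correlated across the scalp
        # (volume conduction) with a small independent sensor component
        pos = spec.montage.positions
        ang = np.arccos(np.clip(pos @ pos.T, -1, 1))
        Ks = np.exp(-(ang**2) / (2 * 0.5**2)) + 1e-6 * np.eye(n_ch)
        chol = np.linalg.cholesky(Ks)
        smooth = _one_over_f_noise(rng, n, n_ch, fs) @ chol.T
        smooth /= smooth.std(axis=0, keepdims=True)
        sensor = _one_over_f_noise(rng, n, n_ch, fs)
        noise = np.sqrt(0.95) * smooth + np.sqrt(0.05) * sensor
        data += noise * math.sqrt(p_noise)
        # mains interference, common phase with per-channel jitter
        tt = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        amp_line = 0.5 * math.sqrt(p_noise) * (0.5 + rng.random(n_ch))
        data += amp_line * np.sin(
            2 * np.pi * spec.line_freq * tt[:, None]
            + phase + 0.1 * rng.standard_normal(n_ch)
        )

    # high-amplitude artifact bursts (to exercise ASR)
    if spec.burst_prob_per_min > 0:
        n_bursts = rng.poisson(spec.burst_prob_per_min * n / fs / 60)
        for _ in range(n_bursts):
            start = rng.integers(0, max(1, n - int(0.5 * fs)))
            length = int(0.5 * fs)
            chans = rng.choice(n_ch, size=3, replace=False)
            win = np.hanning(length)
            for c in chans:
                data[start : start + length, c] += 200.0 * win * rng.choice([-1, 1])

    # bad channels: replaced by uncorrelated white noise
    bad = rng.random(n_ch) < spec.bad_channel_prob
    if bad.any():
        rms = float(np.sqrt(np.mean(data**2)))
        data[:, bad] = rng.standard_normal((n, int(bad.sum()))) * rms

    return Recording(
        data,
        fs,
        list(spec.montage.labels),
        events=[(task_start, spec.trigger_label)],
    )


def simulate_cohort(spec: SimulationSpec, out_dir=None) -> pd.DataFrame:
    """Simulate the full two-group cohort.

    Returns a manifest DataFrame (subject, group, trial, path).  When
    ``out_dir`` is given, one BrainVision triplet per subject-trial is
    written there along with ``manifest.tsv``; otherwise the Recording
    objects are kept in the ``recording`` column.
    """
    import pathlib

    if out_dir is not None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for group, count in (("expert", spec.n_experts), ("novice", spec.n_novices)):
        for sid in range(count):
            for trial in range(spec.trials_per_subject):
                rec = simulate_subject(spec, group, sid, trial)
                row = {
                    "subject": f"{group[0]}{sid:02d}",
                    "group": group,
                    "trial": trial,
                }
                if out_dir is not None:
                    name = f"sub-{group[0]}{sid:02d}_trial{trial}.eeg"
                    path = write_recording(rec, out_dir / name, "brainvision")
                    row["path"] = str(path)
                else:
                    row["recording"] = rec
                rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def make_transient_channel_epochs(
    n_per_class: int = 100,
    montage: Montage | None = None,
    fs: float = 120.0,
    duration_s: float = 3.0,
    transient_frac: float = 0.2,
    signal_amp: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Channel-space epochs whose group difference is purely temporal.

    Both groups carry the same oscillatory topography (the left-posterior
    prototype) at equal total energy, but experts concentrate it in a
    random contiguous ``transient_frac`` of the window while novices
    spread it uniformly.  Whole-window variance features are therefore
    blind to the difference; only temporally resolved models (e.g. a CNN
    with temporal attention) can separate the groups.  Both groups share
    spatially correlated 1/f background.  Returns (epochs, labels) with
    epochs of shape (2 n, samples, channels).
    """
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    n_samp = int(round(duration_s * fs))
    proto = make_prototype_bank(montage, 6, 0)[3]
    pos = montage.positions
    ang = np.arccos(np.clip(pos @ pos.T, -1, 1))
    chol = np.linalg.cholesky(
        np.exp(-(ang**2) / (2 * 0.5**2)) + 1e-6 * np.eye(n_ch)
    )
    epochs, labels = [], []
    for i in range(2 * n_per_class):
        expert = i < n_per_class
        noise = _one_over_f_noise(rng, n_samp, n_ch, fs) @ chol.T
        noise /= noise.std()
        x = noise.copy()
        if expert:  # concentrated burst
            w = max(1, int(round(transient_frac * n_samp)))
            start = rng.integers(0, n_samp - w + 1)
            sl, amp = slice(start, start + w), signal_amp
        else:  # same energy spread over the whole window
            sl, amp = slice(0, n_samp), signal_amp * np.sqrt(transient_frac)
        w = sl.stop - sl.start
        osc = np.sin(
            2 * np.pi * rng.uniform(8, 12) * np.arange(w) / fs
            + rng.uniform(0, 2 * np.pi)
        )
        x[sl] += amp * osc[:, None] * proto
        epochs.append(x - x.mean(axis=1, keepdims=True))
        labels.append("expert" if expert else "novice")
    order = rng.permutation(2 * n_per_class)
    return (
        np.array(epochs)[order],
        [labels[i] for i in order],
    )


# --------------------------------------------------------------------------
# planted-signature tensor datasets (CNN branch ground truth)
# --------------------------------------------------------------------------

def make_planted_tensor_dataset(
    n_per_class: int = 200,
    grid: int = 16,
    depth: int = 360,
    quadrant: str = "lower-left",
    signal_amp: float = 1.0,
    noise_amp: float = 1.0,
    transient_frac: float | None = None,
    seed: int = 0,
):
    """Tensor dataset whose group difference lives in one spatial quadrant.

    Experts carry an oscillatory bump confined to ``quadrant`` of the
    16x16 grid (novices carry none); both classes share smooth spatially
    correlated noise.  With ``transient_frac`` the bump is present only in
    a random contiguous fraction of the temporal axis — the regime where
    temporal attention should outperform whole-window variance features.

    Returns an :class:`~skillstate.tensorize.EEGTensorDataset`.
    """
    from scipy.ndimage import gaussian_filter

    from .tensorize import EEGTensorDataset

    rng = np.random.default_rng(seed)
    half = grid // 2
    rows, cols = {
        "lower-left": (slice(half, grid), slice(0, half)),
        "lower-right": (slice(half, grid), slice(half, grid)),
        "upper-left": (slice(0, half), slice(0, half)),
        "upper-right": (slice(0, half), slice(half, grid)),
    }[quadrant]
    bump = np.zeros((grid, grid))
    bump[rows, cols] = 1.0
    bump = gaussian_filter(bump, sigma=1.5)

    tensors = np.empty((2 * n_per_class, grid, grid, depth), dtype=np.float32)
    labels = []
    tt = np.arange(depth)
    for i in range(2 * n_per_class):
        expert = i < n_per_class
        noise = rng.standard_normal((grid, grid, depth))
        noise = gaussian_filter(noise, sigma=(2.0, 2.0, 1.0))
        noise *= noise_amp / noise.std()
        x = noise
        if expert:
            freq = rng.uniform(0.05, 0.12)
            osc = np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
            gate = np.ones(depth)
            if transient_frac is not None:
                w = max(1, int(round(transient_frac * depth)))
                start = rng.integers(0, depth - w + 1)
                gate = np.zeros(depth)
                gate[start : start + w] = 1.0
            x = x + signal_amp * bump[:, :, None] * (osc * gate)[None, None, :]
        tensors[i] = x
        labels.append("expert" if expert else "novice")

    order = rng.permutation(2 * n_per_class)
    n = 2 * n_per_class
    return EEGTensorDataset(
        tensors=tensors[order],
        labels=np.array(labels)[order],
        subject=np.arange(n)[order] % (2 * n_per_class),
        trial=np.zeros(n, dtype=int),
        window=np.arange(n)[order],
        fs=120.0,
    )
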