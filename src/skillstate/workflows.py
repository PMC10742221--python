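"""End-to-end drivers tying the stages into the two classification
branches.  These are the same code paths the command-line interface runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import csp as csp_mod
from . import microstate as ms
from . import preprocess as pp
from . import tensorize as tz
from .evaluate import ClassifierReport
from .io import Montage, Recording, RunManifest, read_recording
from .synth import SimulationSpec, simulate_cohort

__all__ = [
    "load_cohort",
    "preprocess_cohort",
    "fit_cohort_microstates",
    "csp_branch",
    "tensorize_cohort",
]


def load_cohort(manifest: pd.DataFrame) -> list[tuple[str, str, int, Recording]]:
    """Materialize (subject, group, trial, Recording) tuples from a cohort
    manifest holding either in-memory recordings or file paths."""
    out = []
    for _, row in manifest.iterrows():
        rec = (
            row["recording"]
            if "recording" in row and isinstance(row.get("recording"), Recording)
            else read_recording(row["path"])
        )
        out.append((row["subject"], row["group"], int(row["trial"]), rec))
    return out


def preprocess_cohort(
    cohort: list[tuple[str, str, int, Recording]],
    montage: Montage,
    cfg: pp.PreprocessConfig | None = None,
    manifest: RunManifest | None = None,
):
    """Run the cleaning chain per recording; inadmissible subjects are
    dropped.  Returns (entries, qc) where each entry is
    (subject, group, trial, EpochSet)."""
    cfg = cfg or pp.PreprocessConfig()
    entries, qc = [], {}
    for subject, group, trial, rec in cohort:
        epochs, subject_qc = pp.run_pipeline(rec, montage, cfg, manifest)
        qc[f"{subject}/t{trial}"] = subject_qc
        if epochs is None:
            continue
        epochs.subject, epochs.group, epochs.trial = subject, group, trial
        entries.append((subject, group, trial, epochs))
    return entries, qc


def fit_cohort_microstates(
    entries,
    K: int | None = 6,
    n_init: int = 20,
    seed: int = 0,
    K_range=range(2, 9),
) -> ms.MicrostateModel:
    """Prototype fitting on the aggregated cohort (all groups' task epochs
    concatenated, as in group-level microstate analysis).  Fixed ``K``
    fits that model directly; ``K=None`` scans ``K_range`` by the CV
    criterion."""
    data = np.concatenate(
        [e.epochs.reshape(-1, e.epochs.shape[-1]) for _, _, _, e in entries]
    )
    if K is None:
        return ms.select_model(
            data, entries[0][3].fs, K_range, n_init=n_init, seed=seed
        )
    fs = entries[0][3].fs
    peaks = ms.pick_gfp_peaks(ms.gfp(data), fs, seed=seed)
    return ms.modified_kmeans(data[peaks], K, n_init=n_init, seed=seed)


def csp_branch(
    entries,
    model: ms.MicrostateModel | None = None,
    conditioned: bool = True,
    state: int | str = "modal",
    smooth: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    n_pairs: int = 1,
) -> ClassifierReport:
    """Microstate-conditioned (or plain) regularized CSP + LDA with k-fold
    cross-validation over subject-trial epochs."""
    smooth = {"window_ms": 30} if smooth is None else smooth
    epochs, labels = [], []
    for _, group, _, eset in entries:
        for ep in eset.epochs:
            epochs.append(ep)
            labels.append(group)
    if conditioned:
        if model is None:
            raise ValueError("microstate model required for conditioning")
        segs = [
            ms.backfit(ep, model, smooth=smooth or None, fs=entries[0][3].fs)
            for ep in epochs
        ]
        epochs = csp_mod.microstate_condition(epochs, segs, state)
    return csp_mod.crossvalidate_csp_lda(
        epochs, labels, folds=folds, seed=seed, alpha=alpha, n_pairs=n_pairs
    )


def tensorize_cohort(
    cohort: list[tuple[str, str, int, Recording]],
    montage: Montage,
    task_s: float | None = None,
    pre_s: float = tz.PRE_TRIGGER_S,
    cfg: pp.PreprocessConfig | None = None,
    grid: int = 16,
) -> tz.EEGTensorDataset:
    """Continuous cleaning + 120 Hz tensorization of the task period.

    Each recording is resampled, high-passed, line-cleaned, repaired,
    average-referenced, brought to the tensor rate, and epoched from
    ``pre_s`` seconds before the task trigger through the task; windows
    become 16 x 16 x 360 tensors.
    """
    cfg = cfg or pp.PreprocessConfig()
    epochs = []
    for subject, group, trial, rec in cohort:
        r = pp.resample(rec, cfg.target_fs)
        r = pp.highpass(r, cfg.hp_cutoff, cfg.hp_transition)
        r = pp.remove_line_noise(r, cfg.line_freq)
        flagged = pp.detect_bad_channels(
            r, montage, cfg.bad_channel_corr_threshold, cfg.flatline_s
        )
        if not pp.subject_admissible(flagged, cfg.max_bad_channels):
            continue
        r = pp.interpolate_channels(r, montage, flagged)
        r = pp.average_reference(r)
        r = pp.resample(r, tz.TENSOR_FS)
        if task_s is None:
            trig = r.event_samples(cfg.trigger_label)[0]
            span_s = (r.n_samples - trig) / r.fs + pre_s
        else:
            span_s = task_s + pre_s
        eset = pp.extract_task_epochs(
            r, cfg.trigger_label, onset_s=-pre_s, duration_s=span_s
        )
        for ep in eset.epochs:
            epochs.append((subject, group, trial, ep))
    return tz.build_dataset(epochs, montage, grid)
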