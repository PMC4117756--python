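"""Benchmarking idealizations against simulator ground truth.

The camera observes the state path only at frame resolution, so the
natural comparison is per frame: sample the true state label at every
frame time, do the same for the idealized annotation, and ask that any
disagreement lie within one frame of a true state transition.  Substeps
that contain no frame sample at all (dwells shorter than the frame
time) are unresolvable by construction and appear only as boundary
frames here.
"""

from __future__ import annotations

import numpy as np

from .substep_segmentation import TraceAnnotation
from .synthetic_data import StatePath

_UNBOUND = "none"
_BOUND = ("A", "U", "S", "R")


def truth_frame_labels(path: StatePath, n_frames: int, frame_s: float) -> np.ndarray:
    """Ground-truth substep label per frame ('none' outside bound states)."""
    times = np.arange(n_frames) * frame_s
    raw = path.labels_at(times)
    return np.where(np.isin(raw, _BOUND), raw, _UNBOUND)


def annotation_frame_labels(ann: TraceAnnotation, n_frames: int, frame_s: float) -> np.ndarray:
    """Idealized substep label per frame ('none' outside binding events)."""
    labels = np.full(n_frames, _UNBOUND, dtype=object)
    times = np.arange(n_frames) * frame_s
    for ev in ann.events:
        for seg in ev.segments:
            m = (times >= seg.t_start - 1e-9) & (times < seg.t_end - 1e-9)
            labels[m] = seg.label
    return labels.astype(str)


def frame_label_agreement(
    path: StatePath, ann: TraceAnnotation, n_frames: int, frame_s: float
) -> dict:
    """Compare an idealization with ground truth at frame resolution.

    Returns the fraction of agreeing frames, a boolean pass flag that
    tolerates disagreements only within +/- 1 frame of a true state
    transition, and the raw mismatch count.
    """
    truth = truth_frame_labels(path, n_frames, frame_s)
    det = annotation_frame_labels(ann, n_frames, frame_s)
    mismatch = truth != det
    change = np.flatnonzero(truth[1:] != truth[:-1]) + 1  # transition frames
    near = np.zeros(n_frames, dtype=bool)
    for c in change:
        near[max(c - 1, 0) : min(c + 2, n_frames)] = True
    ok = bool(np.all(near[mismatch]))
    return {
        "agreement": 1.0 - mismatch.mean() if n_frames else 1.0,
        "within_one_frame": ok,
        "n_mismatch": int(mismatch.sum()),
        "n_frames": n_frames,
    }
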