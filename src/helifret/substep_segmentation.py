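"""Idealize bound intervals into the A/U/S/R substeps and emit dwells.

Within one binding event (delimited by total-intensity steps) the FRET
trajectory is a two-level system with linear ramps: a low plateau before
the first unwinding attempt (activation, A), a gradual rise to the high
plateau (unwinding, U), a high plateau (stall, S), an instantaneous drop
on rewinding, and further low plateaus between cycles (reactivation, R).
A versus R is purely positional: the first low plateau after binding is
A, all later ones are R.

Boundary placement: U is bracketed by the crossings of two mid-band
thresholds on a median-filtered FRET series, then extrapolated linearly
to the measured plateau levels, which removes the bias a plain threshold
crossing would introduce on a finite-slope ramp.  All boundaries are
snapped to the frame grid; a dwell spanning frames ``[a, b)`` has
duration ``(b - a) * frame_s``.  The last segment of every event is
censored: whatever ended the event (dissociation, strand separation,
photobleaching or the end of the recording) truncated it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .trace_processing import FretTrace, StepEvent, _robust_sigma


@dataclass
class Thresholds:
    """Band definitions and filter settings for substep idealization."""

    low_max: float = 0.4     # ceiling of the low-FRET band
    high_min: float = 0.6    # floor of the high-FRET band
    median_width: int = 3    # frames; filter used for segmentation only
    min_ramp_frames: int = 2  # minimum length of a trailing censored ramp
    e_low_level: float | None = 0.2    # known plateau levels of the construct;
    e_high_level: float | None = 0.8   # set None to estimate them from data

    def validate(self) -> None:
        if not 0.0 < self.low_max < self.high_min < 1.0:
            raise ValueError("need 0 < low_max < high_min < 1 (non-overlapping bands)")
        if self.median_width < 1 or self.median_width % 2 == 0:
            raise ValueError("median_width must be an odd positive integer")
        if self.min_ramp_frames < 1:
            raise ValueError("min_ramp_frames must be >= 1")


@dataclass
class SubSeg:
    label: str
    t_start: float
    t_end: float
    censored: bool = False

    @property
    def dwell(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SubstepAnnotation:
    """Idealized substeps of one binding event."""

    molecule_id: int
    event_index: int
    t_wait_start: float       # origin of this event's binding wait
    t_bind: float
    t_end: float
    terminal_class: str       # dissociated | separated_or_bleached | trace_end
    segments: list[SubSeg] = field(default_factory=list)
    multi_binder: bool = False

    @property
    def total_bound_s(self) -> float:
        return self.t_end - self.t_bind


@dataclass
class TraceAnnotation:
    """All binding events of one molecule plus the trace extent."""

    molecule_id: int
    trace_end_s: float        # end of the valid (un-bleached) signal
    events: list[SubstepAnnotation] = field(default_factory=list)


def count_cycles(annotation: SubstepAnnotation) -> int:
    """Completed U->S pairs within one binding event."""
    labels = [s.label for s in annotation.segments]
    return sum(
        1 for i, lab in enumerate(labels[:-1]) if lab == "U" and labels[i + 1] == "S"
    )


def _blocks(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[cuts + 1]])
    ends = np.concatenate([idx[cuts] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_alternating(low_b, high_b) -> tuple[list, list]:
    """Merge band blocks so that low and high strictly alternate.

    Consecutive same-band blocks separated only by mid-band frames are
    fused; mid-band excursions that never reach the other band are thus
    absorbed into the surrounding plateau.
    """
    tagged = sorted(
        [(s, e, "low") for s, e in low_b] + [(s, e, "high") for s, e in high_b]
    )
    merged: list[list] = []
    for s, e, band in tagged:
        if merged and merged[-1][2] == band:
            merged[-1][1] = e
        else:
            merged.append([s, e, band])
    lows = [(s, e) for s, e, b in merged if b == "low"]
    highs = [(s, e) for s, e, b in merged if b == "high"]
    return lows, highs


def _cross_time(ef, i, level, dt):
    """Time at which the filtered E crosses ``level`` between frames i, i+1."""
    e0, e1 = ef[i], ef[i + 1]
    if e1 == e0:
        return (i + 1) * dt
    f = np.clip((level - e0) / (e1 - e0), 0.0, 1.0)
    return (i + f) * dt


def _bound_intervals(
    fret_trace: FretTrace, step_events: list[StepEvent]
) -> tuple[list[tuple[int, int, str, bool]], int]:
    """Pair up/down steps into bound intervals.

    Returns (intervals, n_valid_end) where each interval is
    (start_frame, end_frame, terminal_class, multi_binder).
    """
    n_valid = int(fret_trace.valid.sum())  # mask is monotone
    intervals = []
    open_f = None
    multi = False
    for ev in step_events:
        if ev.frame >= n_valid and open_f is None:
            break
        if ev.direction == "up":
            if open_f is None:
                open_f, multi = ev.frame, False
            else:
                multi = True  # second binder on an already-bound molecule
        else:
            if open_f is not None:
                end = min(ev.frame, n_valid)
                term = (
                    "dissociated"
                    if ev.event_class == "dissociation"
                    else "separated_or_bleached"
                )
                if end > open_f:
                    intervals.append((open_f, end, term, multi))
                open_f = None
    if open_f is not None and n_valid > open_f:
        term = "trace_end" if n_valid == fret_trace.n_frames else "separated_or_bleached"
        intervals.append((open_f, n_valid, term, multi))
    return intervals, n_valid


def segment_substeps(
    fret_trace: FretTrace,
    step_events: list[StepEvent],
    thresholds: Thresholds | None = None,
) -> TraceAnnotation:
    """Idealize every bound interval of one trace into A/U/S/R segments.

    A trace with no bound interval yields an annotation with no events
    (not an error).
    """
    th = thresholds or Thresholds()
    th.validate()
    dt = fret_trace.frame_s
    intervals, n_valid = _bound_intervals(fret_trace, step_events)
    ann = TraceAnnotation(fret_trace.molecule_id, n_valid * dt)
    for k, (f0, f1, term, multi) in enumerate(intervals):
        segs = _segment_interval(fret_trace, f0, f1, th)
        t_wait = 0.0 if k == 0 else intervals[k - 1][1] * dt
        ann.events.append(
            SubstepAnnotation(
                molecule_id=fret_trace.molecule_id,
                event_index=k,
                t_wait_start=t_wait,
                t_bind=f0 * dt,
                t_end=f1 * dt,
                terminal_class=term,
                segments=segs,
                multi_binder=multi,
            )
        )
    return ann


def _segment_interval(ft: FretTrace, f0: int, f1: int, th: Thresholds) -> list[SubSeg]:
    dt = ft.frame_s
    raw = ft.e_raw[f0:f1]
    sigma_raw = _robust_sigma(raw)
    # the filter width is matched to the noise level: on (near-)noiseless
    # data smoothing only erases genuine single-frame features
    if sigma_raw > 1e-6 and th.median_width > 1:
        ef = median_filter(raw, size=th.median_width, mode="nearest")
    else:
        ef = raw.copy()
    nloc = f1 - f0
    sigma = _robust_sigma(ef)
    delta = max(1e-9, 3.0 * sigma)
    low_b, high_b = _merge_alternating(
        _blocks(ef < th.low_max), _blocks(ef > th.high_min)
    )
    # plateau levels: the configured construct levels when given (ramp
    # frames inside the bands would otherwise bias a plain data median),
    # else estimated from the banded frames
    if th.e_low_level is not None:
        e_low_hat = th.e_low_level
    else:
        low_frames = np.concatenate([ef[s:e] for s, e in low_b]) if low_b else ef
        e_low_hat = float(np.median(low_frames))
    if th.e_high_level is not None:
        e_high_ref = th.e_high_level
    elif high_b:
        e_high_ref = float(np.median(np.concatenate([ef[s:e] for s, e in high_b])))
    else:
        e_high_ref = th.high_min

    def snap(t: float) -> int:
        return int(round(t / dt))

    if not high_b:
        segs = _low_only_segments(ef, f0, f1, e_low_hat, delta, th, dt)
        if segs:
            segs[-1].censored = True
        return segs

    # --- locate each unwinding ramp around its high block ---
    u_bounds: list[tuple[int, int, float | None, bool]] = []
    prev_end = 0
    for h0, h1 in high_b:
        below = np.flatnonzero(ef[prev_end:h0] <= th.low_max)
        j1 = prev_end + below[-1] if below.size else None
        if j1 is not None and j1 + 1 < nloc:
            tau1 = _cross_time(ef, j1, th.low_max, dt)
        else:
            tau1 = prev_end * dt
        tau2 = _cross_time(ef, h0 - 1, th.high_min, dt) if h0 > prev_end else h0 * dt
        slope = (th.high_min - th.low_max) / (tau2 - tau1) if tau2 > tau1 else None
        if slope and slope > 0:
            u_start = tau1 - max(th.low_max - e_low_hat, 0.0) / slope
            u_end = tau2 + max(e_high_ref - th.high_min, 0.0) / slope
        else:
            u_start, u_end = tau1, tau2
        u_start = max(u_start, prev_end * dt)
        u_end = min(u_end, h1 * dt)
        uf0 = min(max(snap(u_start), prev_end + 1), h0)
        uf1 = max(snap(u_end), uf0 + 1)
        uf1 = min(uf1, h1 - 1) if h1 - 1 > uf0 else min(uf1, h1)
        trunc = h1 == nloc and _is_truncated_ramp(ef, h0, h1, e_high_ref, delta)
        u_bounds.append((uf0, uf1, slope, trunc))
        prev_end = h1

    # --- assemble A (U S R)* with the trailing region handled last ---
    segs: list[SubSeg] = []
    t0 = f0 * dt
    segs.append(SubSeg("A", t0, (f0 + u_bounds[0][0]) * dt))
    for k, ((h0, h1), (uf0, uf1, _slope, trunc)) in enumerate(zip(high_b, u_bounds)):
        if trunc:
            segs.append(SubSeg("U", (f0 + uf0) * dt, f1 * dt))
            break
        segs.append(SubSeg("U", (f0 + uf0) * dt, (f0 + uf1) * dt))
        segs.append(SubSeg("S", (f0 + uf1) * dt, (f0 + h1) * dt))
        if k + 1 < len(u_bounds):
            segs.append(SubSeg("R", (f0 + h1) * dt, (f0 + u_bounds[k + 1][0]) * dt))
        elif h1 < nloc:
            tail = _low_only_segments(
                ef[h1:], f0 + h1, f1, e_low_hat, delta, th, dt, first_label="R"
            )
            segs.extend(tail)
    segs = [s for s in segs if s.t_end > s.t_start or s.label == "S"]
    if segs:
        segs[-1].censored = True
    return segs


def _is_truncated_ramp(ef, h0, h1, e_high_ref, delta) -> bool:
    """Is a terminal high block a still-rising (censored) unwinding ramp?

    True when the block end never reaches the high plateau, i.e. the
    ramp was cut before the stall was entered.
    """
    block = ef[h0:h1]
    tail = block[-min(3, block.size):]
    return bool(tail.mean() < e_high_ref - delta)


def _low_only_segments(
    ef_region, f_abs0, f1, e_low_hat, delta, th, dt, first_label="A"
) -> list[SubSeg]:
    """A low plateau possibly ending in a nascent (censored) ramp."""
    above = ef_region > e_low_hat + delta
    n = ef_region.size
    j2 = n - 1
    while j2 >= 0 and above[j2]:
        j2 -= 1
    n_rise = n - 1 - j2
    if n_rise >= th.min_ramp_frames and j2 >= 0:
        plateau_end = (f_abs0 + j2 + 1) * dt
        return [
            SubSeg(first_label, f_abs0 * dt, plateau_end),
            SubSeg("U", plateau_end, f1 * dt),
        ]
    return [SubSeg(first_label, f_abs0 * dt, f1 * dt)]


@dataclass
class DwellTable:
    """Tidy dwell records plus per-event summaries.

    ``dwells`` columns: condition, substep, dwell_s, censored,
    molecule_id, event_index, cycle_index.
    ``events`` columns: condition, molecule_id, event_index, t_bind,
    t_end, total_bound_s, bound_censored, n_cycles, terminal_class.
    """

    dwells: pd.DataFrame
    events: pd.DataFrame

    def uncensored(self, substep: str, condition: str | None = None) -> np.ndarray:
        d = self.dwells
        m = (d["substep"] == substep) & (~d["censored"])
        if condition is not None:
            m &= d["condition"] == condition
        return d.loc[m, "dwell_s"].to_numpy()

    def bound_times(self, condition: str | None = None, uncensored_only: bool = True):
        e = self.events
        m = ~e["bound_censored"] if uncensored_only else np.ones(len(e), bool)
        if condition is not None:
            m &= e["condition"] == condition
        return e.loc[m, "total_bound_s"].to_numpy()


_DWELL_COLS = [
    "condition", "substep", "dwell_s", "censored",
    "molecule_id", "event_index", "cycle_index",
]
_EVENT_COLS = [
    "condition", "molecule_id", "event_index", "t_bind", "t_end",
    "total_bound_s", "bound_censored", "n_cycles", "terminal_class",
]


def extract_dwells(
    annotations: list[TraceAnnotation],
    condition_key: str = "",
    origin_s: float = 0.0,
) -> DwellTable:
    """Pool substep dwells and per-event summaries over many traces.

    The binding wait (B) of the first event is measured from ``origin_s``
    (time of reagent addition; non-zero for preloading protocols), and
    from the previous dissociation for later events.  Traces that never
    bind contribute a censored B record.  Zero-length segments carry no
    dwell information and are skipped.
    """
    drec, erec = [], []
    for tr in annotations:
        if not tr.events:
            if tr.trace_end_s > origin_s:
                drec.append((condition_key, "B", tr.trace_end_s - origin_s, True,
                             tr.molecule_id, 0, 0))
            continue
        for ev in tr.events:
            wait0 = origin_s if ev.event_index == 0 else ev.t_wait_start
            b_dwell = ev.t_bind - wait0
            if b_dwell > 0:
                drec.append((condition_key, "B", b_dwell, False,
                             tr.molecule_id, ev.event_index, 0))
            cyc = 0
            prev_end = ev.t_bind
            for seg in ev.segments:
                if seg.t_start < prev_end - 1e-9:
                    raise ValueError(
                        f"overlapping segments in molecule {tr.molecule_id} "
                        f"event {ev.event_index}"
                    )
                prev_end = seg.t_end
                if seg.label == "U":
                    cyc += 1
                if seg.dwell > 0:
                    drec.append((condition_key, seg.label, seg.dwell, seg.censored,
                                 tr.molecule_id, ev.event_index, cyc))
            erec.append((condition_key, tr.molecule_id, ev.event_index, ev.t_bind,
                         ev.t_end, ev.total_bound_s,
                         ev.terminal_class != "dissociated",
                         count_cycles(ev), ev.terminal_class))
        last = tr.events[-1]
        if last.terminal_class == "dissociated" and tr.trace_end_s > last.t_end:
            drec.append((condition_key, "B", tr.trace_end_s - last.t_end, True,
                         tr.molecule_id, last.event_index + 1, 0))
    return DwellTable(
        pd.DataFrame(drec, columns=_DWELL_COLS),
        pd.DataFrame(erec, columns=_EVENT_COLS),
    )
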