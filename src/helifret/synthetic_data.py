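"""Ground-truthed synthetic smFRET traces of repetitive helicase unwinding.

One molecule is a continuous-time Markov chain over the states

    unbound --(k_on*[RHA])--> A --(k_act)--> U --(k_unw_eff)--> S
        S --(k_stall)--> instantaneous rewind --> R --(k_react)--> U ...

with three competing global processes: dissociation (``k_off``, active in
every bound state, returns the molecule to the unbound pool), terminal
strand separation (probability ``p_sep`` at the end of each completed
stall, the unlabeled strand diffuses away and the spot goes dark) and
photobleaching (``k_bleach``, spot goes dark).

The observation model renders the state path to two-channel intensities
at fixed camera framing: FRET sits at ``E_low`` in all bound non-U states,
ramps linearly from ``E_low`` to ``E_high`` across each unwinding dwell,
holds at ``E_high`` during the stall and drops back instantaneously on
rewinding.  Total intensity is ``I_total`` when unbound and
``pife_gamma * I_total`` while the protein is bound (protein-induced
fluorescence enhancement), and zero-mean background after bleaching or
strand separation.  Independent Gaussian noise is added per channel per
frame; intensities are not clipped, so noisy frames may go negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import Condition, SimulationParams, effective_rates

BOUND_LABELS = ("A", "U", "S", "R")
TERMINAL_LABELS = ("separated", "bleached")


def _exp_draw(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


@dataclass
class Segment:
    """One contiguous stretch of a state path.

    ``e_start``/``e_end`` are only meaningful for U segments, where they
    record the realized FRET ramp (a dwell cut short by dissociation or
    bleaching ends below ``E_high``).
    """

    label: str
    t_start: float
    t_end: float
    e_start: float | None = None
    e_end: float | None = None

    @property
    def dwell(self) -> float:
        return self.t_end - self.t_start


@dataclass
class StatePath:
    """Ground-truth trajectory of one molecule.

    Segments partition ``[0, duration]`` contiguously; ``terminal`` is
    ``"separated"``, ``"bleached"`` or ``"trace_end"``; ``cycle_seps``
    records, per completed U-S cycle, whether it ended in strand
    separation.
    """

    molecule_id: int
    segments: list[Segment]
    terminal: str
    cycle_seps: list[bool] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.segments[-1].t_end if self.segments else 0.0

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        """State label sampled at each time (right-open segments)."""
        starts = np.array([s.t_start for s in self.segments])
        idx = np.searchsorted(starts, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        labels = np.array([s.label for s in self.segments])
        return labels[idx]

    def to_frame(self) -> pd.DataFrame:
        end = self.duration
        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "label": [s.label for s in self.segments],
                "t_start": [s.t_start for s in self.segments],
                "t_end": [s.t_end for s in self.segments],
                # a segment cut by the end of the recording is censored
                "censored": [
                    s.t_end >= end and s.label not in TERMINAL_LABELS
                    for s in self.segments
                ],
            }
        )


@dataclass
class IntensityTrace:
    """Per-frame two-channel intensities of one molecule."""

    molecule_id: int
    frame_s: float
    I_D: np.ndarray
    I_A: np.ndarray

    def __post_init__(self):
        self.I_D = np.asarray(self.I_D, dtype=float)
        self.I_A = np.asarray(self.I_A, dtype=float)
        if self.I_D.shape != self.I_A.shape:
            raise ValueError("donor and acceptor channels must have equal length")

    @property
    def n_frames(self) -> int:
        return self.I_D.size

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "frame": np.arange(self.n_frames),
                "time_s": self.time_s,
                "I_D": self.I_D,
                "I_A": self.I_A,
            }
        )


def _draw_state_path(
    rng: np.random.Generator,
    params: SimulationParams,
    rates: dict[str, float],
    t_total: float,
    molecule_id: int,
) -> StatePath:
    """Gillespie draw of the state path on [0, t_total]."""
    segs: list[Segment] = []
    cycle_seps: list[bool] = []
    terminal = "trace_end"
    t_bleach = _exp_draw(rng, rates["bleach"])
    t = 0.0
    while t < t_total:
        # --- unbound: wait for binding, bleaching may pre-empt it ---
        t_bind = t + _exp_draw(rng, rates["b"])
        if t_bleach <= min(t_bind, t_total):
            segs.append(Segment("B", t, t_bleach))
            segs.append(Segment("bleached", t_bleach, t_total))
            terminal = "bleached"
            break
        if t_bind >= t_total:
            segs.append(Segment("B", t, t_total))
            break
        segs.append(Segment("B", t, t_bind))
        t = t_bind
        t_off = t + _exp_draw(rng, rates["off"])
        state = "A"
        leave = None  # None: still bound; else "off"/"bleached"/"end"/"separated"
        while leave is None:
            t_cut = min(t_off, t_bleach, t_total)
            if state in ("A", "R"):
                dwell = _exp_draw(rng, rates["a" if state == "A" else "r"])
                t_next = t + dwell
                if t_next <= t_cut:
                    segs.append(Segment(state, t, t_next))
                    t = t_next
                    state = "U"
                else:
                    segs.append(Segment(state, t, t_cut))
                    t = t_cut
                    leave = "cut"
            elif state == "U":
                dwell = _exp_draw(rng, rates["u"])
                t_next = t + dwell
                if t_next <= t_cut:
                    segs.append(Segment("U", t, t_next, params.E_low, params.E_high))
                    t = t_next
                    state = "S"
                else:
                    if math.isfinite(dwell) and dwell > 0:
                        frac = (t_cut - t) / dwell
                        e_cut = params.E_low + frac * (params.E_high - params.E_low)
                    else:
                        e_cut = params.E_low
                    # keep the intended ramp slope for the truncated dwell
                    segs.append(Segment("U", t, t_cut, params.E_low, e_cut))
                    t = t_cut
                    leave = "cut"
            elif state == "S":
                dwell = _exp_draw(rng, rates["s"])
                t_next = t + dwell
                if t_next <= t_cut:
                    segs.append(Segment("S", t, t_next))
                    t = t_next
                    sep = rng.random() < params.p_sep
                    cycle_seps.append(sep)
                    if sep:
                        leave = "separated"
                    else:
                        state = "R"  # instantaneous rewind
                else:
                    segs.append(Segment("S", t, t_cut))
                    t = t_cut
                    leave = "cut"
        if leave == "separated":
            segs.append(Segment("separated", t, t_total))
            terminal = "separated"
            break
        # a "cut" is whichever of dissociation / bleach / trace end came first
        if t >= t_total and t_bleach > t_total and t_off > t_total:
            break
        if t == t_bleach and t_bleach <= t_off:
            segs.append(Segment("bleached", t, t_total))
            terminal = "bleached"
            break
        # dissociation: back to the unbound pool, loop continues
    return StatePath(molecule_id, segs, terminal, cycle_seps)


def _render_trace(
    rng: np.random.Generator,
    params: SimulationParams,
    path: StatePath,
    n_frames: int,
    t0: float,
    molecule_id: int,
) -> IntensityTrace:
    tf = t0 + np.arange(n_frames) * params.frame_s
    e = np.full(n_frames, params.E_low)
    total = np.full(n_frames, params.I_total)
    for seg in path.segments:
        m = (tf >= seg.t_start) & (tf < seg.t_end)
        if not m.any():
            continue
        if seg.label == "B":
            pass
        elif seg.label in ("A", "R", "S"):
            total[m] = params.pife_gamma * params.I_total
            e[m] = params.E_high if seg.label == "S" else params.E_low
        elif seg.label == "U":
            total[m] = params.pife_gamma * params.I_total
            span = seg.t_end - seg.t_start
            frac = (tf[m] - seg.t_start) / span if span > 0 else 0.0
            e[m] = seg.e_start + frac * (seg.e_end - seg.e_start)
        else:  # separated / bleached: dark
            total[m] = 0.0
    i_a = e * total
    i_d = total - i_a
    if params.sigma_noise > 0:
        i_d = i_d + rng.normal(0.0, params.sigma_noise, n_frames)
        i_a = i_a + rng.normal(0.0, params.sigma_noise, n_frames)
    return IntensityTrace(molecule_id, params.frame_s, i_d, i_a)


def _shift_clip_path(path: StatePath, t0: float, duration: float) -> StatePath:
    """Re-express a state path relative to the recording start."""
    if t0 == 0:
        return path
    segs = []
    for s in path.segments:
        a, b = s.t_start - t0, s.t_end - t0
        if b <= 0 or a >= duration:
            continue
        e0, e1 = s.e_start, s.e_end
        if s.label == "U" and e0 is not None and s.t_end > s.t_start:
            span = s.t_end - s.t_start
            e0 = s.e_start + max(0.0, -a) / span * (s.e_end - s.e_start)
            e1 = s.e_start + min(span, duration - a) / span * (s.e_end - s.e_start)
        segs.append(Segment(s.label, max(a, 0.0), min(b, duration), e0, e1))
    return StatePath(path.molecule_id, segs, path.terminal, path.cycle_seps)


def simulate_trace(
    params: SimulationParams,
    condition: Condition,
    duration_s: float,
    seed,
    molecule_id: int = 0,
    record_start_s: float = 0.0,
) -> tuple[IntensityTrace, StatePath]:
    """Simulate one molecule and render its camera trace.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; the
    same seed and parameters always reproduce the identical trace.
    ``record_start_s`` lets the chemistry run for a burn-in period before
    frame 0 (used for population snapshots); the returned state path is
    re-expressed relative to the recording start.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if record_start_s < 0:
        raise ValueError("record_start_s must be >= 0")
    rates = effective_rates(params, condition)  # validates both inputs
    rng = np.random.default_rng(seed)
    t_total = record_start_s + duration_s
    n_frames = int(round(duration_s / params.frame_s))
    path = _draw_state_path(rng, params, rates, t_total, molecule_id)
    trace = _render_trace(rng, params, path, n_frames, record_start_s, molecule_id)
    return trace, _shift_clip_path(path, record_start_s, duration_s)


@dataclass
class SimulatedDataset:
    """Traces, ground truth and manifest for a grid of conditions."""

    conditions: list[Condition]
    traces: dict[str, list[IntensityTrace]]
    truth: dict[str, list[StatePath]]
    manifest: dict

    def traces_frame(self, key: str) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.traces[key]], ignore_index=True)

    def truth_frame(self, key: str) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.truth[key]], ignore_index=True)


def simulate_dataset(
    params: SimulationParams,
    conditions: Sequence[Condition],
    n_molecules: int,
    duration_s: float,
    seed: int,
    record_start_s: float = 0.0,
) -> SimulatedDataset:
    """Batch wrapper: ``n_molecules`` independent traces per condition.

    Per-molecule random streams are spawned deterministically from the
    root seed, so a dataset is reproducible molecule-by-molecule.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("condition list must not be empty")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(conditions))
    traces: dict[str, list[IntensityTrace]] = {}
    truth: dict[str, list[StatePath]] = {}
    for cond, cond_ss in zip(conditions, children):
        key = cond.key()
        mol_seeds = cond_ss.spawn(n_molecules)
        tr, pa = [], []
        for i, ss in enumerate(mol_seeds):
            t, p = simulate_trace(
                params, cond, duration_s, ss, molecule_id=i,
                record_start_s=record_start_s,
            )
            tr.append(t)
            pa.append(p)
        traces[key] = tr
        truth[key] = pa
    manifest = {
        "seed": int(seed),
        "n_molecules": int(n_molecules),
        "duration_s": float(duration_s),
        "record_start_s": float(record_start_s),
        "params": params.to_dict(),
        "conditions": {c.key(): c.to_dict() for c in conditions},
    }
    return SimulatedDataset(conditions, traces, truth, manifest)


@dataclass
class AnnealingTimecourse:
    """Counts of annealed (high-FRET) molecules at snapshot times."""

    condition_key: str
    times_s: np.ndarray
    annealed: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.annealed = np.asarray(self.annealed, dtype=int)
        self.total = np.asarray(self.total, dtype=int)
        if np.any(self.annealed > self.total):
            raise ValueError("annealed counts cannot exceed totals")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition_key,
                "time_s": self.times_s,
                "annealed": self.annealed,
                "total": self.total,
            }
        )


def annealing_rate_for(params: SimulationParams, condition: Condition, include_atp: bool) -> float:
    """Annealing rate implied by a condition: 0 without protein,
    binding-induced without ATP, unwinding-induced with ATP."""
    if condition.rha_conc == 0:
        return 0.0
    return params.k_anneal_unwind if include_atp else params.k_anneal_bind


def simulate_annealing_field(
    params: SimulationParams,
    condition: Condition,
    n_molecules: int,
    snapshot_times: Sequence[float],
    include_atp: bool,
    seed,
) -> tuple[AnnealingTimecourse, np.ndarray]:
    """Surface-field annealing experiment.

    Each surface-tethered duplex acquires its complementary strand at an
    exponential time with the condition's annealing rate; snapshots count
    how many molecules have turned high-FRET.  Returns the timecourse and
    the per-molecule ground-truth annealing times.
    """
    params.validate()
    condition.validate()
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    snaps = np.asarray(snapshot_times, dtype=float)
    if snaps.size < 2 or np.any(np.diff(snaps) <= 0):
        raise ValueError("need >= 2 strictly increasing snapshot times")
    rate = annealing_rate_for(params, condition, include_atp)
    rng = np.random.default_rng(seed)
    if rate > 0:
        t_anneal = rng.exponential(1.0 / rate, n_molecules)
    else:
        t_anneal = np.full(n_molecules, np.inf)
    counts = (t_anneal[:, None] <= snaps[None, :]).sum(axis=0)
    key = condition.key() + ("_atp" if include_atp else "_noatp")
    tc = AnnealingTimecourse(key, snaps, counts, np.full(snaps.size, n_molecules))
    return tc, t_anneal


def separation_fraction_theory(params: SimulationParams, condition: Condition) -> float:
    """Closed-form fraction of binding events that end in strand separation.

    Competing exponentials make each substep survive dissociation with
    probability k/(k+k_off); a completed cycle separates with ``p_sep``.
    Summing the geometric series over cycles (no bleaching, no censoring):

        P(sep) = pA * pU * pS * p_sep / (1 - (1-p_sep) * pU * pS * pR)
    """
    r = effective_rates(params, condition)
    off = r["off"]
    pa = r["a"] / (r["a"] + off)
    pu = r["u"] / (r["u"] + off)
    ps = r["s"] / (r["s"] + off)
    pr = r["r"] / (r["r"] + off)
    a = pu * ps
    return pa * a * params.p_sep / (1.0 - (1.0 - params.p_sep) * a * pr)
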