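import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import helifret as hf
from helifret.params import effective_rates

BOUND = {"A", "U", "S", "R"}


def test_absorbing_state_after_binding(wt_params):
    """With every rate but k_on zero, the first binding is absorbing: the
    trace sits at E_low with PIFE-enhanced total intensity forever."""
    p = dataclasses.replace(
        wt_params, k_act=0.0, k_unw=0.0, k_stall=0.0, k_react=0.0,
        k_off=0.0, k_bleach=0.0, p_sep=0.0, sigma_noise=0.0,
    )
    trace, path = hf.simulate_trace(p, hf.Condition(), 60.0, seed=5)
    labels = [s.label for s in path.segments]
    assert labels[0] == "B" and labels[1] == "A" and len(labels) == 2
    bound = trace.time_s >= path.segments[1].t_start
    total = trace.I_D + trace.I_A
    e = trace.I_A / total
    assert np.allclose(total[bound], p.pife_gamma * p.I_total)
    assert np.allclose(e[bound], p.E_low)


def test_noiseless_intensity_arithmetic(wt_params):
    """sigma_noise=0, pife_gamma=1.5, I_total=200 -> bound total exactly 300."""
    p = dataclasses.replace(wt_params, sigma_noise=0.0, pife_gamma=1.5,
                            I_total=200.0, k_bleach=0.0)
    trace, path = hf.simulate_trace(p, hf.Condition(), 120.0, seed=8)
    labels = path.labels_at(trace.time_s)
    total = trace.I_D + trace.I_A
    assert np.allclose(total[np.isin(labels, list(BOUND))], 300.0)
    assert np.allclose(total[labels == "B"], 200.0)


def test_noiseless_fret_matches_generating_efficiency(noiseless_params):
    """Per-frame I_A/(I_D+I_A) reproduces the generating E to 1e-12."""
    trace, path = hf.simulate_trace(noiseless_params, hf.Condition(), 200.0, seed=3)
    total = trace.I_D + trace.I_A
    alive = total > 0
    e = trace.I_A[alive] / total[alive]
    # reconstruct the generating efficiency from the state path
    expected = np.full(trace.n_frames, noiseless_params.E_low)
    for seg in path.segments:
        m = (trace.time_s >= seg.t_start) & (trace.time_s < seg.t_end)
        if seg.label == "S":
            expected[m] = noiseless_params.E_high
        elif seg.label == "U":
            span = seg.t_end - seg.t_start
            expected[m] = seg.e_start + (trace.time_s[m] - seg.t_start) / span * (
                seg.e_end - seg.e_start
            )
    assert np.max(np.abs(e - expected[alive])) < 1e-12


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_state_path_partitions_time(wt_params, seed):
    """Segments tile [0, duration] contiguously; U is followed by S and S
    by R unless the path was cut; exactly one terminal segment."""
    trace, path = hf.simulate_trace(wt_params, hf.Condition(), 120.0, seed=seed)
    segs = path.segments
    assert segs[0].t_start == 0.0
    assert segs[-1].t_end == pytest.approx(120.0)
    for a, b in zip(segs[:-1], segs[1:]):
        assert a.t_end == pytest.approx(b.t_start)
        assert a.t_end > a.t_start or a.label in ("B",)
    terminals = [s for s in segs if s.label in ("separated", "bleached")]
    assert len(terminals) <= 1
    if terminals:
        assert segs[-1] is terminals[0]
    # grammar of completed transitions
    for a, b in zip(segs[:-1], segs[1:]):
        if a.label == "U":
            assert b.label in ("S", "B", "bleached", "separated")
        if a.label == "S":
            assert b.label in ("R", "B", "bleached", "separated")


def test_dwell_means_match_generating_rates(wt_params, wt_condition):
    """Pooled ground-truth dwells agree with the generating exponential
    for every substep (mean within 3 SE; completed dwells follow the
    competing-risk rate k + k_off + k_bleach)."""
    rates = effective_rates(wt_params, wt_condition)
    comp = rates["off"] + rates["bleach"]
    gen = {"A": rates["a"] + comp, "U": rates["u"] + comp,
           "S": rates["s"] + comp, "R": rates["r"] + comp}
    pools = {k: [] for k in gen}
    follow = {"A": "U", "U": "S", "S": ("R", "separated"), "R": "U"}
    n_events = 0
    for i in range(250):
        _, path = hf.simulate_trace(wt_params, wt_condition, 250.0,
                                    np.random.SeedSequence([77, i]))
        segs = path.segments
        n_events += sum(1 for s in segs if s.label == "A")
        for j, s in enumerate(segs[:-1]):
            if s.label in pools and segs[j + 1].label in follow[s.label]:
                pools[s.label].append(s.dwell)
    assert n_events >= 250
    for label, dwells in pools.items():
        d = np.asarray(dwells)
        assert d.size >= 200, label
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - 1.0 / gen[label]) < 3 * se, label


def test_binding_wait_is_exponential_in_concentration(wt_params):
    """Mean first-binding wait tracks 1/(k_on [RHA]) within 3 SE."""
    cond = hf.Condition(rha_conc=20e-9)
    waits = []
    p = dataclasses.replace(wt_params, k_bleach=0.0)
    for i in range(400):
        _, path = hf.simulate_trace(p, cond, 400.0, np.random.SeedSequence([5, i]))
        if len(path.segments) > 1:
            waits.append(path.segments[0].t_end)
    w = np.asarray(waits)
    expected = 1.0 / (wt_params.k_on * 20e-9)
    se = w.std(ddof=1) / np.sqrt(w.size)
    assert abs(w.mean() - expected) < 3 * se + 0.05 * expected


def test_separation_fraction_matches_geometric_competition(wt_params, wt_condition):
    """Fraction of binding events ending in strand separation converges
    to the closed-form geometric-competition probability."""
    p = dataclasses.replace(wt_params, k_bleach=0.0)
    theory = hf.separation_fraction_theory(p, wt_condition)
    n_sep = n_events = 0
    for i in range(300):
        _, path = hf.simulate_trace(p, wt_condition, 600.0,
                                    np.random.SeedSequence([9, i]))
        labels = [s.label for s in path.segments]
        starts = [j for j, lab in enumerate(labels) if lab == "A"]
        for j in starts:
            # censored events (running into the trace end) are skipped
            end = next((lab for lab in labels[j:] if lab in ("B", "separated")), None)
            if end is not None:
                n_events += 1
                n_sep += end == "separated"
    frac = n_sep / n_events
    se = np.sqrt(theory * (1 - theory) / n_events)
    assert n_events > 300
    assert abs(frac - theory) < 3 * se


def test_wild_type_cycles_per_event_in_reported_band(wt_dwell_table):
    """Median completed unwinding cycles per binding event falls in the
    2-10 range characteristic of repetitive unwinding."""
    cycles = wt_dwell_table.events["n_cycles"]
    assert 2 <= cycles.median() <= 10


def test_dataset_determinism_and_shape(wt_params, wt_condition):
    ds1 = hf.simulate_dataset(wt_params, [wt_condition], 3, 30.0, 42)
    ds2 = hf.simulate_dataset(wt_params, [wt_condition], 3, 30.0, 42)
    key = wt_condition.key()
    assert [t.molecule_id for t in ds1.traces[key]] == [0, 1, 2]
    f1, f2 = ds1.traces_frame(key), ds2.traces_frame(key)
    assert f1.equals(f2)
    assert f1.to_csv(index=False) == f2.to_csv(index=False)


def test_dataset_manifest_records_grid(wt_params):
    conds = [hf.Condition(atp_conc=a) for a in (10e-6, 100e-6, 1e-3)]
    ds = hf.simulate_dataset(wt_params, conds, 2, 10.0, 0)
    atps = sorted(c["atp_conc"] for c in ds.manifest["conditions"].values())
    assert atps == [10e-6, 100e-6, 1e-3]


def test_dataset_input_validation(wt_params, wt_condition):
    with pytest.raises(ValueError):
        hf.simulate_dataset(wt_params, [], 3, 10.0, 0)
    with pytest.raises(ValueError):
        hf.simulate_dataset(wt_params, [wt_condition], 0, 10.0, 0)
    with pytest.raises(ValueError):
        hf.simulate_trace(wt_params, wt_condition, -5.0, seed=0)


def test_annealing_field_controls(wt_params):
    snaps = [10.0, 50.0, 200.0]
    no_protein = hf.Condition(rha_conc=0.0, atp_conc=0.0)
    tc, _ = hf.simulate_annealing_field(wt_params, no_protein, 500, snaps, False, 1)
    assert np.all(tc.annealed == 0)
    # near-instant annealing saturates at the first snapshot
    fast = dataclasses.replace(wt_params, k_anneal_unwind=1e4)
    tc2, _ = hf.simulate_annealing_field(fast, hf.Condition(), 500, snaps, True, 1)
    assert tc2.annealed[0] == 500
    with pytest.raises(ValueError):
        hf.simulate_annealing_field(wt_params, hf.Condition(), 0, snaps, True, 1)
    with pytest.raises(ValueError):
        hf.simulate_annealing_field(wt_params, hf.Condition(), 10, [5.0], True, 1)


def test_annealing_times_follow_exponential_cdf(wt_params):
    """Empirical annealing-time distribution matches 1 - exp(-kt)."""
    _, times = hf.simulate_annealing_field(
        wt_params, hf.Condition(), 2000, [100.0, 200.0], True, 123
    )
    k = wt_params.k_anneal_unwind
    res = stats.ks_1samp(times, stats.expon(scale=1.0 / k).cdf)
    assert res.pvalue > 0.01
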