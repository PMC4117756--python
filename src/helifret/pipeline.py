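"""End-to-end composition: simulate -> process -> segment -> fit -> report.

:func:`run_pipeline` drives the whole chain for a grid of conditions and
emits a machine-readable report: per-condition substep rates, an
association-constant fit when several protein concentrations are
present, a Michaelis-Menten fit when several ATP concentrations are
present, and (optionally) the annealing comparison.  Everything is
deterministic under the configured seed, and the report records the
package version, the seed and a hash of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .annealing_analysis import (annealing_fraction_curve, enhancement_factor,
                                 estimate_annealing_rate)
from .io import config_hash, write_dwell_table, write_json, write_traces, write_truth
from .params import Condition, SimulationParams, preset_params
from .rate_inference import (fit_association_constant, fit_michaelis_menten,
                             rates_from_dwell_table)
from .substep_segmentation import (DwellTable, Thresholds, extract_dwells,
                                   segment_substeps)
from .synthetic_data import simulate_annealing_field, simulate_dataset
from .trace_processing import compute_fret, detect_intensity_steps


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Concentrations are taken in the units experimentalists quote (nM
    protein, uM ATP) and converted to molar internally.
    """

    variant: str = "wild_type"
    rha_nM: tuple = (40.0,)
    atp_uM: tuple = (1000.0,)
    n_molecules: int = 50
    duration_s: float = 240.0
    seed: int = 0
    temperature_label: str = "RT"
    gc_fraction: float = 0.5
    param_overrides: dict = field(default_factory=dict)
    step_window: int = 8
    step_alpha: float = 0.05
    low_max: float = 0.4
    high_min: float = 0.6
    run_annealing: bool = False
    annealing_n: int = 1000
    annealing_snapshots: tuple = (30.0, 60.0, 120.0, 240.0, 480.0, 900.0)
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not self.rha_nM or not self.atp_uM:
            raise ValueError("need at least one RHA and one ATP concentration")
        self.params().validate()
        self.conditions()[0].validate()

    def params(self) -> SimulationParams:
        p = preset_params(self.variant)
        known = {f.name for f in fields(SimulationParams)}
        unknown = set(self.param_overrides) - known
        if unknown:
            raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
        for k, v in self.param_overrides.items():
            setattr(p, k, float(v))
        p.validate()
        return p

    def conditions(self) -> list[Condition]:
        return [
            Condition(self.variant, c * 1e-9, a * 1e-6,
                      self.temperature_label, self.gc_fraction)
            for c in self.rha_nM
            for a in self.atp_uM
        ]

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def analyze_traces(
    traces,
    thresholds: Thresholds | None = None,
    condition_key: str = "",
    window: int = 8,
    alpha: float = 0.05,
) -> DwellTable:
    """Process raw traces of one condition into a dwell table."""
    annotations = []
    for tr in traces:
        ft = compute_fret(tr)
        steps = detect_intensity_steps(ft, window=window, alpha=alpha)
        annotations.append(segment_substeps(ft, steps, thresholds))
    return extract_dwells(annotations, condition_key=condition_key)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain for one configuration; return the report dict."""
    config.validate()
    params = config.params()
    conditions = config.conditions()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    dataset = simulate_dataset(
        params, conditions, config.n_molecules, config.duration_s, config.seed
    )
    thresholds = Thresholds(low_max=config.low_max, high_min=config.high_min)
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config.to_dict()),
        "config": config.to_dict(),
        "conditions": {},
    }
    all_rates = []
    for cond in conditions:
        key = cond.key()
        table = analyze_traces(
            dataset.traces[key], thresholds, condition_key=key,
            window=config.step_window, alpha=config.step_alpha,
        )
        rates = rates_from_dwell_table(table)
        all_rates.append((cond, rates))
        cycles = table.events["n_cycles"].to_numpy()
        report["conditions"][key] = {
            "condition": cond.to_dict(),
            "n_events": int(len(table.events)),
            "median_cycles": float(np.median(cycles)) if cycles.size else None,
            "rates": rates.to_dict(orient="records"),
        }
        if out_dir:
            write_traces(dataset.traces[key], out_dir / f"traces_{key}.csv")
            write_truth(dataset.truth[key], out_dir / f"truth_{key}.csv")
            write_dwell_table(table, out_dir / f"dwells_{key}.tsv",
                              out_dir / f"events_{key}.tsv")

    report["association_fit"] = _maybe_association_fit(all_rates)
    report["michaelis_menten_fit"] = _maybe_mm_fit(all_rates)
    if config.run_annealing:
        report["annealing"] = _annealing_block(params, config)
    if out_dir:
        write_json(report, out_dir / "report.json")
    return report


def _rate_for(rates_df, substep):
    row = rates_df[rates_df["substep"] == substep]
    if len(row) != 1:
        return None
    return float(row["rate"].iloc[0]), float(row["sem"].iloc[0])


def _maybe_association_fit(all_rates):
    pts = []
    for cond, rates in all_rates:
        got = _rate_for(rates, "B")
        if got:
            pts.append((cond.rha_conc, *got))
    concs = sorted({p[0] for p in pts})
    if len(concs) < 2:
        return None
    c, y, e = map(np.array, zip(*pts))
    fit = fit_association_constant(c, y, e)
    return {"k_on_M_s": fit.slope, "k_on_se": fit.slope_se,
            "r_squared": fit.r_squared, "n_points": fit.n}


def _maybe_mm_fit(all_rates):
    pts = []
    for cond, rates in all_rates:
        got = _rate_for(rates, "U")
        if got:
            pts.append((cond.atp_conc, *got))
    concs = sorted({p[0] for p in pts})
    if len(concs) < 3:
        return None
    x, y, e = map(np.array, zip(*pts))
    fit = fit_michaelis_menten(x, y, e)
    return {"vmax_s": fit.vmax, "km_M": fit.km, "km_uM": fit.km * 1e6,
            "vmax_se": fit.vmax_se, "km_se_M": fit.km_se,
            "converged": fit.converged}


def _annealing_block(params: SimulationParams, config: RunConfig) -> dict:
    cond = config.conditions()[0]
    snaps = config.annealing_snapshots
    results = {}
    rates = {}
    for i, (tag, include_atp, c) in enumerate((
        ("no_protein", False, Condition(cond.variant, 0.0, 0.0)),
        ("binding_induced", False, cond),
        ("unwinding_induced", True, cond),
    )):
        tc, _ = simulate_annealing_field(
            params, c, config.annealing_n, snaps, include_atp,
            np.random.SeedSequence([config.seed, i]),
        )
        curve = annealing_fraction_curve(tc)
        est = estimate_annealing_rate(curve)
        rates[tag] = est
        results[tag] = {"rate_s": est.rate, "se": est.se,
                        "degenerate": est.degenerate,
                        "endpoint_fraction": est.endpoint_fraction}
    if rates["binding_induced"].rate > 0:
        ef = enhancement_factor(rates["unwinding_induced"], rates["binding_induced"],
                                variant=cond.variant)
        results["enhancement_factor"] = {"factor": ef.factor, "se": ef.se}
    return results
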