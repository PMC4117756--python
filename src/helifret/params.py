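"""Kinetic parameters and experimental conditions.

The simulator and the inference chain share one parameter object,
:class:`SimulationParams`, holding the substep rates of the five-stage
unwinding cycle (binding wait B, activation A, unwinding U, stalling S,
reactivation R), the dissociation and photobleaching rates, and the
observation-model constants (FRET levels, PIFE factor, intensity scale,
camera noise, frame time).  :class:`Condition` describes one experimental
condition: protein variant, protein and ATP concentration, temperature
label and duplex GC fraction.

Numeric defaults for the two variants (``wild_type`` and ``delta_dsRBD``)
live in ``presets.yaml`` next to this module; all of them except the
association constant and the ATP Michaelis constant are model assumptions,
marked as such in the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from importlib import resources

import yaml

VARIANTS = ("wild_type", "delta_dsRBD")

_RATE_FIELDS = (
    "k_on", "k_act", "k_unw", "k_stall", "k_react", "k_off", "k_bleach",
    "k_anneal_bind", "k_anneal_unwind",
)


@dataclass
class SimulationParams:
    """All kinetic rates and observation constants for one variant.

    Rates are per second (``k_on`` per molar per second), concentrations
    molar, intensities in arbitrary camera units.
    """

    k_on: float            # association rate constant, M^-1 s^-1
    k_act: float           # activation rate, s^-1
    k_unw: float           # unwinding completion rate at saturating ATP, s^-1
    Km_atp: float          # Michaelis constant of the ATP dependence, M
    k_stall: float         # stalling exit rate, s^-1
    k_react: float         # reactivation rate, s^-1
    k_off: float           # dissociation rate while bound, s^-1
    p_sep: float           # P(full strand separation) per completed cycle
    E_low: float = 0.2     # FRET of the duplex / rewound state
    E_high: float = 0.8    # FRET of the fully unwound (stalled) state
    pife_gamma: float = 1.5   # total-intensity multiplier while bound (>= 1)
    I_total: float = 200.0    # mean unbound total intensity, a.u.
    sigma_noise: float = 10.0  # per-channel per-frame Gaussian sd, a.u.
    k_bleach: float = 0.001   # photobleaching rate of the dye pair, s^-1
    frame_s: float = 0.1      # frame integration time, s
    temp_factor: float = 3.0  # 37C/RT multiplier on all kinetic rates
    gc_slope: float = 2.0     # exponential GC sensitivity of k_unw, k_stall
    k_anneal_bind: float = 0.002    # binding-induced annealing rate, s^-1
    k_anneal_unwind: float = 0.010  # unwinding-induced annealing rate, s^-1

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be >= 0")
        if self.Km_atp <= 0:
            raise ValueError("Km_atp must be > 0")
        if not 0.0 <= self.p_sep <= 1.0:
            raise ValueError("p_sep must be in [0, 1]")
        if not 0.0 <= self.E_low < self.E_high <= 1.0:
            raise ValueError("need 0 <= E_low < E_high <= 1")
        if self.pife_gamma < 1.0:
            raise ValueError("pife_gamma must be >= 1")
        if self.frame_s <= 0:
            raise ValueError("frame_s must be > 0")
        if self.I_total <= 0 or self.sigma_noise < 0:
            raise ValueError("I_total must be > 0 and sigma_noise >= 0")
        if self.temp_factor <= 0:
            raise ValueError("temp_factor must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Condition:
    """One experimental condition (concentrations in molar)."""

    variant: str = "wild_type"
    rha_conc: float = 40e-9       # M
    atp_conc: float = 1e-3        # M
    temperature_label: str = "RT"  # "RT" or "37C"
    gc_fraction: float = 0.5

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.rha_conc < 0 or self.atp_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if self.temperature_label not in ("RT", "37C"):
            raise ValueError("temperature_label must be 'RT' or '37C'")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")

    def key(self) -> str:
        """Compact condition identifier used in file names and tables."""
        return (
            f"{self.variant}_rha{self.rha_conc * 1e9:g}nM_"
            f"atp{self.atp_conc * 1e6:g}uM_{self.temperature_label}_"
            f"gc{self.gc_fraction * 100:g}"
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _load_preset_table() -> dict:
    text = resources.files("helifret").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_params(variant_name: str) -> SimulationParams:
    """Return the full preset parameter set for a protein variant.

    ``delta_dsRBD`` differs from ``wild_type`` by a lower ``k_on``, a
    higher ``k_act``, a higher ``k_off`` and an unchanged ``k_unw`` --
    the kinetic signature of deleting the two N-terminal dsRNA-binding
    domains.
    """
    table = _load_preset_table()
    if variant_name not in table:
        raise ValueError(
            f"unknown variant {variant_name!r}; expected one of {tuple(table)}"
        )
    params = SimulationParams(**{k: float(v) for k, v in table[variant_name].items()})
    params.validate()
    return params


def params_from_yaml(path) -> dict[str, SimulationParams]:
    """Load a ``{variant: params}`` mapping from a user YAML file."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    known = {f.name for f in fields(SimulationParams)}
    out = {}
    for variant, entries in table.items():
        unknown = set(entries) - known
        if unknown:
            raise ValueError(f"unknown parameter keys for {variant!r}: {sorted(unknown)}")
        p = SimulationParams(**{k: float(v) for k, v in entries.items()})
        p.validate()
        out[variant] = p
    return out


def params_to_yaml(mapping: dict[str, SimulationParams], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v.to_dict() for k, v in mapping.items()}, fh, sort_keys=False)


def effective_rates(params: SimulationParams, condition: Condition) -> dict[str, float]:
    """Condition-resolved transition rates of the kinetic scheme.

    * binding rate ``b`` = ``k_on`` x [RHA] (pseudo-first-order);
    * unwinding rate ``u`` follows Michaelis-Menten in [ATP];
    * at 37C every kinetic rate is multiplied by ``temp_factor``;
    * ``u`` and ``s`` carry an exponential GC-content factor
      ``exp(-gc_slope * (gc - 0.5))`` (AT-rich duplexes unwind faster).
    """
    params.validate()
    condition.validate()
    tf = params.temp_factor if condition.temperature_label == "37C" else 1.0
    gc = math.exp(-params.gc_slope * (condition.gc_fraction - 0.5))
    atp = condition.atp_conc
    u = params.k_unw * atp / (params.Km_atp + atp) if atp > 0 else 0.0
    return {
        "b": tf * params.k_on * condition.rha_conc,
        "a": tf * params.k_act,
        "u": tf * gc * u,
        "s": tf * gc * params.k_stall,
        "r": tf * params.k_react,
        "off": tf * params.k_off,
        "bleach": params.k_bleach,
    }
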