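# Kinetic presets for the five-substep repetitive-unwinding model of RNA
# helicase A (RHA/DHX9) on a surface-tethered dsRNA with a 3' ssRNA tail.
#
# Anchored values:
#   k_on   (wild type)  -- association constant from the binding-rate vs
#                          [RHA] line, 2.61e6 M^-1 s^-1.
#   Km_atp              -- Michaelis constant of the ATP dependence of the
#                          unwinding substep, 26 uM.
# Every other number is a model ASSUMPTION chosen so that the qualitative
# kinetic picture holds: activation is the slowest substep, a wild-type
# binding event runs 2-10 unwinding cycles before the strands separate or
# the enzyme leaves, and the dsRBD-truncation mutant binds slower,
# activates faster, leaves sooner and usually completes a single cycle.
# Rates are s^-1 at room temperature unless noted; concentrations molar.

wild_type:
  k_on: 2.61e6          # M^-1 s^-1, anchored
  k_act: 0.05           # slowest substep (rate-limiting activation)
  k_unw: 0.5            # unwinding completion rate at saturating ATP
  Km_atp: 26.0e-6       # M, anchored
  k_stall: 1.0
  k_react: 0.3
  k_off: 0.005          # long-lived binding -> repetitive cycling
  p_sep: 0.15           # per completed cycle; terminal strand separation
  E_low: 0.2
  E_high: 0.8
  pife_gamma: 1.5       # total-intensity multiplier while bound (PIFE)
  I_total: 200.0        # a.u., unbound total intensity
  sigma_noise: 10.0     # a.u. per channel per frame
  k_bleach: 0.001
  frame_s: 0.1
  temp_factor: 3.0      # 37C / RT multiplier, inside the 2-5x band
  gc_slope: 2.0         # exponential GC sensitivity of k_unw and k_stall
  k_anneal_bind: 0.002    # s^-1, binding-induced annealing (no ATP)
  k_anneal_unwind: 0.010  # s^-1, unwinding-induced annealing (with ATP)

delta_dsRBD:
  k_on: 0.3e6           # lower binding rate than wild type
  k_act: 0.15           # faster activation (dsRBDs inhibit activation)
  k_unw: 0.5            # unchanged relative to wild type
  Km_atp: 26.0e-6
  k_stall: 1.0
  k_react: 0.3
  k_off: 0.04           # higher off rate -> no repetitive unwinding
  p_sep: 0.7            # typically one cycle then the molecule is lost
  E_low: 0.2
  E_high: 0.8
  pife_gamma: 1.5
  I_total: 200.0
  sigma_noise: 10.0
  k_bleach: 0.001
  frame_s: 0.1
  temp_factor: 3.0
  gc_slope: 2.0
  k_anneal_bind: 0.001
  k_anneal_unwind: 0.002
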