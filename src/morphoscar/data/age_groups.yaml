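# Age-group parameter table for the feasibility study.
#
# Group 2 (ages 16-40) uses the healthy-adult mean values unchanged; the
# other groups are generated from those means by multiplicative factors
# encoding the qualitative aging of skin: fibroblast density, (myo)fibroblast
# and signaling-molecule diffusion, proliferation, differentiation,
# fibroblast apoptosis, collagen turnover, and the MMP-inhibition constant
# all decrease with age, while crowding, stiffness, the morphoelastic rate,
# and (past 40) viscosity increase.
#
# The equilibrium collagen concentration declines ~2% per year compounded
# from the group-2 reference age of 28; `collagen_age` is the age at which
# that decline is evaluated for each group.  For the two oldest groups the
# collagen age saturates below the groups' representative ages: the adult
# secretion rate k_c (held fixed across groups) must stay below its
# stability bound delta_c * rho_bar * a_c_I, and compounding the decline to
# ages beyond ~55 would push the healthy-skin equilibrium of the model into
# sustained spontaneous inflammation.  The shrinking margin between k_c and
# its bound in the older groups is itself an aging effect: signaling
# molecules are cleared ever more slowly, which delays and deepens
# contraction.
#
# The wound values (N_tilde, c_tilde, rho_tilde) are the same for every
# group; in particular the initial wound collagen stays at 20% of the adult
# mean 0.1125 g/cm^3.
#
# This table is a package default, deliberately editable: the factors are
# synthesized from qualitative aging rules, not fitted to any cohort.
reference_age: 28
collagen_decline_per_year: 0.02
heterogeneous:
  sd_fraction: 0.10
  parameters: [E, mu, xi, delta_N, delta_M, rho_bar]
groups:
  1:
    age_range: [0, 15]
    collagen_age: 8
    multipliers:
      N_bar: 1.60
      D_F: 1.25
      D_c: 1.25
      r_F: 1.10
      k_F: 1.20
      delta_N: 1.15
      delta_rho: 1.20
      a_c_II: 1.15
      kappa_F: 0.90
      E: 0.90
      zeta: 0.90
      mu: 1.00
  2:
    age_range: [16, 40]
    collagen_age: 28
    multipliers: {}
  3:
    age_range: [41, 70]
    collagen_age: 45
    multipliers:
      N_bar: 0.95
      D_F: 0.85
      D_c: 0.85
      r_F: 0.97
      k_F: 0.95
      delta_N: 0.95
      delta_rho: 0.90
      a_c_II: 0.90
      kappa_F: 1.05
      E: 1.10
      zeta: 1.10
      mu: 1.10
  4:
    age_range: [71, 110]
    collagen_age: 52
    multipliers:
      N_bar: 0.92
      D_F: 0.75
      D_c: 0.75
      r_F: 0.95
      k_F: 0.95
      delta_N: 0.92
      delta_rho: 0.80
      a_c_II: 0.80
      kappa_F: 1.10
      E: 1.20
      zeta: 1.20
      mu: 1.20
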