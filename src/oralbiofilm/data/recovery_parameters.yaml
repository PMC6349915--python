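# Calibrated kinetic parameters for the two-donor recovery study:
# three-week-old biofilms, 10-minute irrigant immersion (CHX, IPI or
# NaOCl), 15-week post-treatment follow-up of the live-cell ratio.
#
# Units: first-order rates (c2, c5, c8, r_a, r_bs, r_dp) 1/s; c3 in 1/s per
# kg/m^3; c_a, c_q in kg/m^3/s; Hill constants (k_q, k_9, k_13) and
# concentration capacities (H_max, Q_max) and A_residual in kg/m^3; L_max,
# E_max, D_pr dimensionless.
#
# Parameter classes: I donor- and agent-independent (H_max, Q_max, c5, c_a,
# k_9, k_q, E_max); II donor-dependent (c2, c_q, r_bs, r_dp, L_max); III
# agent-specific (c3, c8, r_a, k_13, D_pr, A_residual).
#
# A_residual is the post-rinse "leaked" agent concentration carried into
# the recovery phase.
study: recovery
scale:
  t0: 1.0
  C: 8.24e-3
groups:
  donor1:
    CHX:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-6
      c3: 2.06e-1
      c5: 9.9e-1
      c8: 2.0e-5
      c_a: 8.24e-9
      c_q: 1.65e-8
      r_a: 1.8e-7
      r_bs: 1.6e-7
      r_dp: 2.0e-6
      D_pr: 1.6e-2
      k_9: 6.59e-3
      k_13: 2.88e-8
      k_q: 2.47e-3
      L_max: 8.0e-2
      E_max: 1.2e-2
      A_residual: 1.24e-6
    IPI:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-6
      c3: 1.5e-1
      c5: 9.9e-1
      c8: 2.0e-5
      c_a: 8.24e-9
      c_q: 1.65e-8
      r_a: 2.0e-7
      r_bs: 1.6e-7
      r_dp: 2.0e-6
      D_pr: 5.0e-2
      k_9: 6.59e-3
      k_13: 1.48e-8
      k_q: 2.47e-3
      L_max: 8.0e-2
      E_max: 1.2e-2
      A_residual: 9.89e-7
    NaOCl:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-6
      c3: 4.5e-1
      c5: 9.9e-1
      c8: 9.0e-6
      c_a: 8.24e-9
      c_q: 1.65e-8
      r_a: 3.0e-7
      r_bs: 1.6e-7
      r_dp: 2.0e-6
      D_pr: 6.0e-3
      k_9: 6.59e-3
      k_13: 1.48e-8
      k_q: 2.47e-3
      L_max: 8.0e-2
      E_max: 1.2e-2
      A_residual: 1.3e-7
  donor2:
    CHX:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-6
      c3: 1.76e-1
      c5: 9.9e-1
      c8: 2.0e-5
      c_a: 8.24e-9
      c_q: 1.65e-8
      r_a: 8.0e-8
      r_bs: 1.8e-7
      r_dp: 2.0e-6
      D_pr: 2.66e-2
      k_9: 6.59e-3
      k_13: 1.24e-8
      k_q: 2.47e-3
      L_max: 8.0e-2
      E_max: 1.2e-2
      A_residual: 1.03e-7
    IPI:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-6
      c3: 1.40e-1
      c5: 9.9e-1
      c8: 1.0e-5
      c_a: 8.24e-9
      c_q: 1.65e-8
      r_a: 2.4e-7
      r_bs: 1.8e-7
      r_dp: 2.0e-6
      D_pr: 7.0e-2
      k_9: 6.59e-3
      k_13: 1.24e-8
      k_q: 2.47e-3
      L_max: 8.0e-2
      E_max: 1.2e-2
      A_residual: 1.25e-7
    NaOCl:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-6
      c3: 5.81e-1
      c5: 9.9e-1
      c8: 1.0e-5
      c_a: 8.24e-9
      c_q: 1.65e-8
      r_a: 2.7e-7
      r_bs: 1.8e-7
      r_dp: 2.0e-6
      D_pr: 3.5e-3
      k_9: 6.59e-3
      k_13: 1.48e-8
      k_q: 2.47e-3
      L_max: 8.0e-2
      E_max: 1.2e-2
      A_residual: 1.43e-7
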