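# Calibrated kinetic parameters for the aged-biofilm susceptibility study:
# biofilms of age 0-8 weeks treated with CHX, IPI or NaOCl for 1 or 3
# minutes, live-cell ratio read out immediately after the pulse.
#
# Units and parameter classes as in recovery_parameters.yaml.
#
# A_residual: 0.0 — the residual carry-over was not measured in this
# study and never enters it (the readout is immediately post-pulse).
study: aged
scale:
  t0: 1.0
  C: 8.24e-3
groups:
  aged:
    CHX:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-4
      c3: 1.20
      c5: 9.9e-1
      c8: 1.0e-2
      c_a: 8.24e-9
      c_q: 4.94e-9
      r_a: 1.3e-2
      r_bs: 1.6e-7
      r_dp: 5.0e-6
      D_pr: 4.8e-2
      k_9: 6.59e-3
      k_13: 1.48e-8
      k_q: 2.47e-3
      L_max: 1.2e-1
      E_max: 2.2e-1
      A_residual: 0.0
    IPI:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-4
      c3: 2.18e-1
      c5: 9.9e-1
      c8: 1.0e-2
      c_a: 8.24e-9
      c_q: 4.94e-9
      r_a: 1.6e-2
      r_bs: 1.6e-7
      r_dp: 5.0e-6
      D_pr: 2.66e-2
      k_9: 6.59e-3
      k_13: 1.48e-8
      k_q: 2.47e-3
      L_max: 1.2e-1
      E_max: 2.2e-1
      A_residual: 0.0
    NaOCl:
      H_max: 6.59e-4
      Q_max: 2.47e-3
      c2: 3.0e-4
      c3: 8.49
      c5: 9.9e-1
      c8: 6.0e-2
      c_a: 8.24e-9
      c_q: 4.94e-9
      r_a: 2.0e-4
      r_bs: 1.6e-7
      r_dp: 5.0e-6
      D_pr: 1.2e-2
      k_9: 6.59e-3
      k_13: 1.48e-8
      k_q: 2.47e-3
      L_max: 1.2e-1
      E_max: 2.2e-1
      A_residual: 0.0
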