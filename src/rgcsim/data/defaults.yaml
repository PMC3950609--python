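# Default model configuration: every value is the printed model constant.
# Override any key in a user file passed to rgcsim.config.load_config.

membrane:
  C_m: 1.0            # uF/cm^2
  V_K: -70.0          # mV
  V_L: -60.0
  V_h: 0.0
  V_T: 120.0
  V_Na: 35.0
  Ca_e: 1.8e-3        # M
  Ca_diss: 1.0e-6
  Ca_res: 1.0e-7
  r_shell: 0.1        # um
  tau_Ca: 1.5         # ms
  R_gas: 8.314
  F: 9.684e+4
  T_kelvin: 305.15    # 32 C
  gL0: 8.0e-6         # S/cm^2
  gKCa_max: 5.0e-5

# Regional densities in the order
# (soma, dendrite, initial_segment, narrow_segment, socb, distal_axon)
distribution:
  g_Na: [0.08, 0.025, 0.15, 0.2, 0.4, 0.07]
  g_Ca: [0.0015, 0.002, 0.0015, 0.0, 0.0, 0.0]
  g_K: [0.018, 0.012, 0.018, 0.018, 0.0, 0.018]
  g_KA: [0.054, 0.036, 0.054, 0.0, 0.0, 0.0]
  # the distal-axon K(Ca) ceiling of 0.07 S/cm^2 is as printed; override
  # here if treating it as a typo
  g_KCa_max: [6.5e-5, 1.0e-6, 6.5e-5, 6.5e-5, 0.0, 0.07]
  leak_multiplier: [15.0, 15.0, 15.0, 15.0, 15.0, 25.0]
  h_multiplier: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
  nap_multiplier: [1.0, 1.0, 0.05, 0.05, 5.0, 0.05]
  t_multiplier: [1.0, 5.0, 1.0, 1.0, 1.0, 1.0]
  gL0: 8.0e-6

simulation:
  dt: 0.025                  # ms
  axial_resistivity: 110.0   # Ohm cm
  settle_time: 500.0         # ms
  initial_V: -65.0           # mV
  solver: backward_euler
  max_segment_length: 40.0   # um

protocols:
  hyp_step_200pA: {amplitude: -0.2, step_duration: 500.0, pre: 1000.0, post: 500.0}
  staircase_fig9: {increment: -0.02, step_duration: 2000.0, final_amplitude: -0.2, final_duration: 500.0}
  cv_steps: {increment: -0.02, max_amplitude: -0.08, hold_duration: 10000.0}
  on_depolarize: {amplitude: 0.05}
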