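units:
  capacitance: pF
  conductance: nS
  potential: mV
  temperature: degC
c_soma: 142.0
c_axon: 14.2
g_couple: 25.0
e_leak: -91.01065530836671
temperature: 30.0
conductances:
  Na:
  - 3500.0
  - 1400.0
  Kdr:
  - 250.0
  - 125.0
  A:
  - 100.0
  - 0.0
  Kv1:
  - 41.7
  - 23.0
  T:
  - 51.0
  - 0.0
  H:
  - 0.4
  - 0.0
  leak:
  - 0.4796704524229396
  - 0.15989015080764654
channels:
  Na:
    activation_exponent: 3
    inactivation_exponent: 1
    v_half_act: -36.0
    slope_act: 6.5
    v_half_inact: -55.0
    slope_inact: -7.0
    tau_act:
      tau_min: 0.04
      tau_amp: 0.2
      v_mid: -40.0
      slope_rise: 15.0
      slope_fall: 15.0
    tau_inact:
      tau_min: 0.5
      tau_amp: 8.0
      v_mid: -60.0
      slope_rise: 11.0
      slope_fall: 11.0
    e_rev: 50.0
    q10: 3.0
    t_ref: 30.0
  Kdr:
    activation_exponent: 4
    inactivation_exponent: 0
    v_half_act: -25.0
    slope_act: 8.0
    v_half_inact: 0.0
    slope_inact: -1.0
    tau_act:
      tau_min: 0.5
      tau_amp: 20.0
      v_mid: -55.0
      slope_rise: 12.0
      slope_fall: 12.0
    tau_inact:
      tau_min: 1.0
      tau_amp: 0.0
      v_mid: 0.0
      slope_rise: 10.0
      slope_fall: 10.0
    e_rev: -90.0
    q10: 3.0
    t_ref: 30.0
  A:
    activation_exponent: 4
    inactivation_exponent: 1
    v_half_act: -60.0
    slope_act: 8.5
    v_half_inact: -78.0
    slope_inact: -6.0
    tau_act:
      tau_min: 0.5
      tau_amp: 1.5
      v_mid: -60.0
      slope_rise: 20.0
      slope_fall: 20.0
    tau_inact:
      tau_min: 8.0
      tau_amp: 20.0
      v_mid: -75.0
      slope_rise: 15.0
      slope_fall: 15.0
    e_rev: -90.0
    q10: 3.0
    t_ref: 30.0
  Kv1:
    activation_exponent: 1
    inactivation_exponent: 1
    v_half_act: -41.0
    slope_act: 6.0
    v_half_inact: -65.0
    slope_inact: -12.0
    tau_act:
      tau_min: 3.0
      tau_amp: 12.0
      v_mid: -60.0
      slope_rise: 15.0
      slope_fall: 15.0
    tau_inact:
      tau_min: 500.0
      tau_amp: 0.0
      v_mid: 0.0
      slope_rise: 10.0
      slope_fall: 10.0
    e_rev: -90.0
    q10: 3.0
    t_ref: 30.0
  T:
    activation_exponent: 2
    inactivation_exponent: 1
    v_half_act: -57.0
    slope_act: 6.2
    v_half_inact: -81.0
    slope_inact: -4.0
    tau_act:
      tau_min: 0.6
      tau_amp: 3.0
      v_mid: -75.0
      slope_rise: 15.0
      slope_fall: 15.0
    tau_inact:
      tau_min: 20.0
      tau_amp: 200.0
      v_mid: -88.0
      slope_rise: 10.0
      slope_fall: 10.0
    e_rev: 120.0
    q10: 3.0
    t_ref: 30.0
  H:
    activation_exponent: 0
    inactivation_exponent: 1
    v_half_act: 0.0
    slope_act: 1.0
    v_half_inact: -75.0
    slope_inact: -5.5
    tau_act:
      tau_min: 1.0
      tau_amp: 0.0
      v_mid: 0.0
      slope_rise: 10.0
      slope_fall: 10.0
    tau_inact:
      tau_min: 80.0
      tau_amp: 150.0
      v_mid: -80.0
      slope_rise: 15.0
      slope_fall: 15.0
    e_rev: -43.0
    q10: 3.0
    t_ref: 30.0
  leak:
    activation_exponent: 0
    inactivation_exponent: 0
    v_half_act: 0.0
    slope_act: 1.0
    v_half_inact: 0.0
    slope_inact: -1.0
    tau_act:
      tau_min: 1.0
      tau_amp: 0.0
      v_mid: 0.0
      slope_rise: 10.0
      slope_fall: 10.0
    tau_inact:
      tau_min: 1.0
      tau_amp: 0.0
      v_mid: 0.0
      slope_rise: 10.0
      slope_fall: 10.0
    e_rev: -91.01065530836671
    q10: 3.0
    t_ref: 30.0
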