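# Default baseline spiking neuron (no T-type current).
#
# A reduced sodium/potassium/leak spiker with near-instantaneous Na
# activation, tuned to fire tonically over roughly 3-10 uA/cm^2 applied
# current (quiescent at and below ~2.6 uA/cm^2) with its interspike voltage
# trajectory spanning about -71..-50 mV, so that an inserted low-threshold
# calcium window is functionally engaged.  These parameters are an
# engineering baseline, not measurements, and carry no temperature
# dependence by design.
#
# Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
schema_version: 1
baseline:
  c_m: 1.0
  na:
    g_max: 35.0
    e_rev: 55.0
    gates:
      m:
        polarity: activation
        v_half: -35.0
        slope: 9.0
        tau_depol: 0.2
        tau_hyper: 0.2
        tau_v_mid: -40.0
        tau_slope: 10.0
        exponent: 3
      h:
        polarity: inactivation
        v_half: -50.0
        slope: 7.0
        tau_depol: 0.4
        tau_hyper: 5.0
        tau_v_mid: -58.0
        tau_slope: 6.0
        exponent: 1
  k:
    g_max: 12.0
    e_rev: -90.0
    gates:
      n:
        polarity: activation
        v_half: -35.0
        slope: 10.0
        tau_depol: 1.0
        tau_hyper: 3.0
        tau_v_mid: -55.0
        tau_slope: 10.0
        exponent: 4
  leak:
    g_max: 0.5
    e_rev: -65.0
cat_sets: []
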