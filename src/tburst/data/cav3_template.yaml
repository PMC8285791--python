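# Template registry: three Cav3 isoforms x two temperatures (21C, 37C).
#
# The six cat_sets entries below are SYNTHETIC PLACEHOLDERS sharing one
# generic kinetic shape; they are flagged INVALID-until-transcribed in their
# provenance fields.  Replace the numeric fields with published voltage-clamp
# measurements for each isoform and temperature to model real channels; the
# schema and units (mV, ms, mS/cm^2) stay the same.
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
cat_sets:
- isoform: Cav3.1
  temperature: 21C
  provenance: PLACEHOLDER (synthetic) — NOT measured kinetics. Transcribe published
    HEK-cell voltage-clamp values for this isoform/temperature into these fields before
    interpreting any run as that isoform; entries are INVALID-until-transcribed.
  g_max: 0.7
  e_rev: 120.0
  activation:
    polarity: activation
    v_half: -50.0
    slope: 6.0
    tau_depol: 1.5
    tau_hyper: 6.0
    tau_v_mid: -45.0
    tau_slope: 8.0
    exponent: 2
  inactivation:
    polarity: inactivation
    v_half: -75.0
    slope: 6.0
    tau_depol: 25.0
    tau_hyper: 60.0
    tau_v_mid: -70.0
    tau_slope: 6.0
    exponent: 1
- isoform: Cav3.1
  temperature: 37C
  provenance: PLACEHOLDER (synthetic) — NOT measured kinetics. Transcribe published
    HEK-cell voltage-clamp values for this isoform/temperature into these fields before
    interpreting any run as that isoform; entries are INVALID-until-transcribed.
  g_max: 1.4
  e_rev: 120.0
  activation:
    polarity: activation
    v_half: -50.0
    slope: 6.0
    tau_depol: 0.5
    tau_hyper: 2.0
    tau_v_mid: -45.0
    tau_slope: 8.0
    exponent: 2
  inactivation:
    polarity: inactivation
    v_half: -75.0
    slope: 6.0
    tau_depol: 8.333333333333332
    tau_hyper: 20.0
    tau_v_mid: -70.0
    tau_slope: 6.0
    exponent: 1
- isoform: Cav3.2
  temperature: 21C
  provenance: PLACEHOLDER (synthetic) — NOT measured kinetics. Transcribe published
    HEK-cell voltage-clamp values for this isoform/temperature into these fields before
    interpreting any run as that isoform; entries are INVALID-until-transcribed.
  g_max: 0.7
  e_rev: 120.0
  activation:
    polarity: activation
    v_half: -50.0
    slope: 6.0
    tau_depol: 1.5
    tau_hyper: 6.0
    tau_v_mid: -45.0
    tau_slope: 8.0
    exponent: 2
  inactivation:
    polarity: inactivation
    v_half: -75.0
    slope: 6.0
    tau_depol: 25.0
    tau_hyper: 60.0
    tau_v_mid: -70.0
    tau_slope: 6.0
    exponent: 1
- isoform: Cav3.2
  temperature: 37C
  provenance: PLACEHOLDER (synthetic) — NOT measured kinetics. Transcribe published
    HEK-cell voltage-clamp values for this isoform/temperature into these fields before
    interpreting any run as that isoform; entries are INVALID-until-transcribed.
  g_max: 1.4
  e_rev: 120.0
  activation:
    polarity: activation
    v_half: -50.0
    slope: 6.0
    tau_depol: 0.5
    tau_hyper: 2.0
    tau_v_mid: -45.0
    tau_slope: 8.0
    exponent: 2
  inactivation:
    polarity: inactivation
    v_half: -75.0
    slope: 6.0
    tau_depol: 8.333333333333332
    tau_hyper: 20.0
    tau_v_mid: -70.0
    tau_slope: 6.0
    exponent: 1
- isoform: Cav3.3
  temperature: 21C
  provenance: PLACEHOLDER (synthetic) — NOT measured kinetics. Transcribe published
    HEK-cell voltage-clamp values for this isoform/temperature into these fields before
    interpreting any run as that isoform; entries are INVALID-until-transcribed.
  g_max: 0.7
  e_rev: 120.0
  activation:
    polarity: activation
    v_half: -50.0
    slope: 6.0
    tau_depol: 1.5
    tau_hyper: 6.0
    tau_v_mid: -45.0
    tau_slope: 8.0
    exponent: 2
  inactivation:
    polarity: inactivation
    v_half: -75.0
    slope: 6.0
    tau_depol: 25.0
    tau_hyper: 60.0
    tau_v_mid: -70.0
    tau_slope: 6.0
    exponent: 1
- isoform: Cav3.3
  temperature: 37C
  provenance: PLACEHOLDER (synthetic) — NOT measured kinetics. Transcribe published
    HEK-cell voltage-clamp values for this isoform/temperature into these fields before
    interpreting any run as that isoform; entries are INVALID-until-transcribed.
  g_max: 1.4
  e_rev: 120.0
  activation:
    polarity: activation
    v_half: -50.0
    slope: 6.0
    tau_depol: 0.5
    tau_hyper: 2.0
    tau_v_mid: -45.0
    tau_slope: 8.0
    exponent: 2
  inactivation:
    polarity: inactivation
    v_half: -75.0
    slope: 6.0
    tau_depol: 8.333333333333332
    tau_hyper: 20.0
    tau_v_mid: -70.0
    tau_slope: 6.0
    exponent: 1
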