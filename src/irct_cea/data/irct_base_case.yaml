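# Base-case decision model: four surgical strategies for massive
# irreparable rotator cuff tears.  Costs in US$, probabilities are annual
# per-cycle hazards while at risk, utilities are Constant-Murley score / 100.
settings:
  horizon_years: 10
  cycle_length_years: 1.0
  discount_rate: 0.03
  wtp: 50000.0
  n_patients: 1000
  n_iterations: 1000
  revision_cost_uplift: 0.05
  rsa_revision_cost_uplift: null
  sd_fraction_costs: 0.2
  sd_fraction_probs: 0.2
  sd_utilities: 0.05
  allow_repeat_events: false
  rng_seed: 0
conversion_target: RSA
u_failure: 0.35
strategies:
  - name: SCR
    upfront_cost: 20837.0
    p_reoperation: 0.069
    p_conversion: 0.017
    u_success: 0.76
  - name: LTTT
    upfront_cost: 16915.0
    p_reoperation: 0.075
    p_conversion: 0.05
    u_success: 0.67
  - name: SABS
    upfront_cost: 9058.0
    p_reoperation: 0.069
    p_conversion: 0.05
    u_success: 0.69
  - name: RSA
    upfront_cost: 17210.0
    p_reoperation: 0.08
    p_conversion: 0.0
    u_success: 0.59
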