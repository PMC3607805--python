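# Fully commented gammamodes configuration (default values).
# Load with:  gammamodes simulate --config examples/config.yaml --trials 1 --seed 1 --out out/
# Units: mV, ms, nA, uS, nF, MOhm; rates in spikes/s; conductance scales in nS.

neurons:
  excitatory:
    g_K_us: 4.74        # maximal potassium conductance
    g_Na_us: 12.5       # maximal sodium conductance
    g_L_us: 0.025       # leak conductance (tau_m = C_m / g_L = 10 ms)
    V_K_mv: -80.0
    V_Na_mv: 40.0
    V_L_mv: -65.0
    C_m_nf: 0.25
    temperature_c: 34.0 # temperature factor phi = 3^((T - 6.3)/10) ~ 21
  inhibitory:
    g_K_us: 4.74
    g_Na_us: 12.5
    g_L_us: 0.025       # tau_m = 5 ms with the halved capacitance
    V_K_mv: -80.0
    V_Na_mv: 40.0
    V_L_mv: -65.0
    C_m_nf: 0.125
    temperature_c: 34.0

synapses:
  ampa_recurrent:
    tau_r_ms: 0.5       # conductance rise time
    tau_d_ms: 2.0       # conductance decay time
    E_syn_mv: 0.0       # depolarizing reversal
    g_prime_ns: 2.5     # double-exponential scale g'
  ampa_external:
    tau_r_ms: 0.5
    tau_d_ms: 2.0
    E_syn_mv: 0.0
    g_prime_ns: 3.2
  gaba:
    tau_r_ms: 2.0
    tau_d_ms: 5.0       # the decay constant swept in the tau_d experiments
    E_syn_mv: -70.0     # hyperpolarizing reversal
    g_prime_ns: 240.0   # strong inhibition balances the external excitation

network:
  n_neurons: 2000
  frac_exc: 0.8         # 1600 excitatory / 400 inhibitory
  p_connect: 0.1        # independent Bernoulli edges; mean out-degree 200
  delay_mean_ms: 2.0    # gamma-distributed recurrent delays
  delay_variance_ms2: 4.0

drive:
  mean_rate: 8500.0     # external Poisson rate per neuron (spikes/s)
  sigma: 0.6            # OU standard deviation of the rate fluctuation
  tau_ou: 16.0          # OU correlation time; spectral corner ~ 9.9 Hz
  sigma_scale: 1.0      # multiplier on sigma for visible-fluctuation regimes

integration:
  duration_ms: 3000.0   # one trial
  dt_ms: 0.05           # Heun predictor-corrector step
  i_bias_na: 0.0        # optional constant injected current (all neurons)

lfp:
  electrode_resistance_mohm: 1.0  # R_e of the LFP proxy

recording:
  bin_ms: 1.0           # averaging bin for recorded traces (1 kHz analysis rate)
  record_subset: null   # null records every neuron's input and GABA currents
  v_subset: []          # neuron ids whose voltage trace is kept
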