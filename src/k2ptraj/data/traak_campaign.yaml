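# Published run-level summary of the 32 x 1 us TRAAK force-field
# comparison campaign: design labels, recorded conduction events,
# prevalent TM4 gating state and lipid cavity occupancy per replica.
replicas:
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 0,   replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 0,   replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 100, replica: 1, duration_us: 1.0, n_events: 2,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 100, replica: 2, duration_us: 1.0, n_events: 4,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 100, replica: 3, duration_us: 1.0, n_events: 2,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 200, replica: 1, duration_us: 1.0, n_events: 3,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 200, replica: 2, duration_us: 1.0, n_events: 11, prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KK,  voltage_mV: 200, replica: 3, duration_us: 1.0, n_events: 8,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 0,   replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 0,   replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 100, replica: 1, duration_us: 1.0, n_events: 1,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 100, replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 100, replica: 3, duration_us: 1.0, n_events: 2,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 200, replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 200, replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: AMBER,  init_config: KWK, voltage_mV: 200, replica: 3, duration_us: 1.0, n_events: 0,  prevalent_state: up/down, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 0,   replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/down, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 0,   replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: up/down, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 100, replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 100, replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: down/up, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 100, replica: 3, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 200, replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 200, replica: 2, duration_us: 1.0, n_events: 11, prevalent_state: down/up, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KK,  voltage_mV: 200, replica: 3, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 0,   replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/down, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 0,   replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: up/down, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 100, replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 100, replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 100, replica: 3, duration_us: 1.0, n_events: 0,  prevalent_state: up/up,   lipids_in_cavity: false}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 200, replica: 1, duration_us: 1.0, n_events: 0,  prevalent_state: down/up, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 200, replica: 2, duration_us: 1.0, n_events: 0,  prevalent_state: down/up, lipids_in_cavity: true}
  - {force_field: CHARMM, init_config: KWK, voltage_mV: 200, replica: 3, duration_us: 1.0, n_events: 0,  prevalent_state: up/down, lipids_in_cavity: true}
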