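# Annotated default configuration for the re-entry-location study.
# All lengths in mm, times in s, pressures in Pa, velocities in m/s.

geometry:
  proximal_length: 60.0        # undissected segment carrying the branch slots
  dissected_length: 225.0      # fits the most proximal (202.3 mm) re-entry case
  distal_length: 20.0
  true_lumen_width: 20.0
  false_lumen_short_axis: 12.8 # 50% sizing rule then gives 6.4 mm tears
  septum_thickness: 2.0
  entry_tear_width: 6.4
  entry_tear_offset: 5.0       # tear center, mm from dissection start
  branch_slots:
    - {axial_position: 15.0, width: 6.0, outflow_fraction: 0.05}
    - {axial_position: 30.0, width: 6.0, outflow_fraction: 0.05}
    - {axial_position: 45.0, width: 6.0, outflow_fraction: 0.05}

cases: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]

waveforms:
  period: 1.0                  # cardiac cycle length
  branches: true               # false: drop slots, scale inlet to 85%
  inlet:                       # half-sine systolic pulse, peak at 0.25 s
    peak: 1.0
    systole_start: 0.05
    systole_end: 0.45
    baseline: 0.0
  outlet:                      # arterial pressure wave, ~80-120 mmHg
    diastolic: 10600.0
    systolic: 16000.0
    peak_phase: 0.30

fluid:
  density: 1060.0              # kg/m^3
  dynamic_viscosity: 0.00371   # Pa.s

numerics:
  spacing_mm: 1.0              # default sweep resolution; 0.5 for fine runs
  cfl_safety: 0.3
  dt_max_ms: 1.0
  n_cycles: 4                  # report the final (quasi-periodic) cycle
  snapshot_phases_s: [0.25, 0.47]   # peak systole / early diastole
  n_correctors: 2
  re_critical: 2300.0

post:
  recirculation_threshold: 0.01    # reversed if u < -threshold * reference
  reference_speed: 1.0             # m/s, the inlet peak

output:
  directory: results
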