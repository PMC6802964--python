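# Default parameter sets for the simulators. Presets are data, not code:
# kinetic means describe the study conditions each scenario emulates, and
# the variability entries set the event-to-event spread of those kinetics.
#
# Event kinetics: rates in molecules/s, durations in s. The plateau means
# are chosen so that the implied mean event duration (rise + plateau +
# fall, averaged over the kinetic variability) equals the condition's
# reported mean T_dur.

cameras:
  endocytosis:       # 20 fps endocytic-patch imaging at reduced (20%) excitation
    pixel_size: 0.1
    frame_interval: 0.05
    psf_sigma: 0.12
    single_fluorophore_intensity: 52.7
    read_noise_sd: 10.0
    shot_noise: true
    baseline_offset: 100.0
  single_molecule:   # 63 fps single-molecule imaging at full excitation;
                     # short exposures and TIRF sectioning keep the
                     # background an order of magnitude below patch scenes
    pixel_size: 0.1
    frame_interval: 0.015873015873015872
    psf_sigma: 0.12
    single_fluorophore_intensity: 263.5
    read_noise_sd: 4.0
    shot_noise: true
    baseline_offset: 30.0

calibration:
  # Single-molecule calibration scenes use full excitation; endocytosis
  # scenes use 20% — linear-excitation scaling between the two.
  excitation_scale: 0.2

events:
  myo1:
    camera: endocytosis
    kinetics:
      rise_rate: 13.0
      peak_molecules: 45.0
      plateau_duration: 7.10
      fall_rate: 14.0
      scission_mode: none
    variability:
      peak_cv: 0.25
      plateau_sd: 2.2
      rate_cv: 0.10
  cam1:
    camera: endocytosis
    kinetics:
      rise_rate: 38.0
      peak_molecules: 90.0
      plateau_duration: 6.33
      fall_rate: 40.0
      scission_mode: none
    variability:
      peak_cv: 0.22
      plateau_sd: 1.0
      rate_cv: 0.12
  myo1_S742A:
    camera: endocytosis
    kinetics:
      rise_rate: 13.0
      peak_molecules: 45.0
      plateau_duration: 5.56
      fall_rate: 14.0
      scission_mode: none
    variability:
      peak_cv: 0.25
      plateau_sd: 1.84
      rate_cv: 0.10
  cam2:
    camera: endocytosis
    kinetics:
      rise_rate: 5.0
      peak_molecules: 30.0
      plateau_duration: 60.0   # effectively open-ended; scission terminates the event
      fall_rate: 30.0
      scission_mode: abrupt
      scission_offset: 11.4
    variability:
      peak_cv: 0.15
      plateau_sd: 0.0
      rate_cv: 0.10
      scission_sd: 1.5
      scission_min: 9.0

two_color:
  cam1_myo1:      # Myo1 and Cam1 co-arrive; Cam1 leaves ~3 s earlier
    channel_a: myo1
    channel_b: cam1
    offset_b: 0.0
  cam1_cam2:      # Cam2 scission ~11.4 s after the shared event start
    channel_a: cam1
    channel_b: cam2
    offset_b: 0.0

single_molecule:
  camera: single_molecule
  on_rate_density: 0.075   # events / um^2 / s
  off_rate: 7.8            # 1/s
  diffusion_coefficient: 0.03  # um^2/s

titrations:
  cam1_titration:
    model: {K1: 0.05, K2: 0.68, dF1: 23.02, dF2: 23.03, F0: 10.0, reporter_total: 0.5}
    ligand_concentrations: [0.0, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0]
    noise_cv: 0.02
  cam2_titration:
    model: {K1: 0.05, K2: 1.10, dF1: 9.0, dF2: 21.0, F0: 10.0, reporter_total: 0.5}
    ligand_concentrations: [0.0, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0]
    noise_cv: 0.02
  pca_titration:
    model: {pCa50: 5.87, hill_n: 2.0, Ymax: 100.0, Ymin: 20.0}
    pca_values: [4.5, 4.93, 5.36, 5.79, 6.21, 6.64, 7.07, 7.5]
    noise_cv: 0.02

transients:
  ca_release:
    amplitudes: [0.4, 0.4, 0.4]
    rates: [137.0, 12.9, 2.0]
    offset: 0.1
    noise_sd: 0.008
    duration: 2.5
    dense_until: 0.06
    dense_rate: 10000.0
    sparse_rate: 400.0
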