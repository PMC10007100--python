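# Calibrated soil hydraulic profiles.
#
# oued_souhil: sandy-loam experimental plot, five 0.2 m layers to 1 m,
# van Genuchten-Mualem parameters from inverse calibration against in-situ
# water content and salinity monitoring.
oued_souhil:
  layers:
    - {z_top: 0.0, z_bot: 0.2, theta_r: 0.036,  theta_s: 0.3938, alpha_vg: 3.32, n_vg: 1.69, k_sat: 2.0}
    - {z_top: 0.2, z_bot: 0.4, theta_r: 0.0555, theta_s: 0.3947, alpha_vg: 4.0,  n_vg: 1.60, k_sat: 1.0}
    - {z_top: 0.4, z_bot: 0.6, theta_r: 0.0515, theta_s: 0.3571, alpha_vg: 3.14, n_vg: 1.50, k_sat: 0.28}
    - {z_top: 0.6, z_bot: 0.8, theta_r: 0.051,  theta_s: 0.3416, alpha_vg: 4.0,  n_vg: 1.23, k_sat: 0.125}
    - {z_top: 0.8, z_bot: 1.0, theta_r: 0.0507, theta_s: 0.3388, alpha_vg: 1.0,  n_vg: 1.40, k_sat: 0.68}
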