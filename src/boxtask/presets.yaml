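# Calibrated group presets: agent behaviour + covariate model per group.
# Values chosen by coarse grid search (scripts/calibrate_presets.py) so that
# study-sized simulated cohorts reproduce the published group means of
# between-search errors, completion times and ACE-III totals.
AD:
  agent:
    latency_mu: 1.503
    latency_sd: 0.35
    rho_between: 0.72
    rho_within: 0.99
    sigma_scan: 0.4
  covariate_model:
    loadings:
      ace_total: -3.0
      ace_visuospatial: -0.8
      rcf_copy: -1.5
      rcf_copy_time: 30.0
      rcf_recall: -2.9
      spatial_span_backward: -0.4
      spatial_span_forward: -0.3
      trails_a_time: 10.0
      trails_b_time: 15.0
    means:
      ace_total: 68.3
      ace_visuospatial: 12.5
      rcf_copy: 24.9
      rcf_copy_time: 282.2
      rcf_recall: 3.0
      spatial_span_backward: 4.3
      spatial_span_forward: 5.5
      trails_a_time: 68.0
      trails_b_time: 170.0
    sds:
      ace_total: 10.5
      ace_visuospatial: 3.4
      rcf_copy: 8.5
      rcf_copy_time: 141.3
      rcf_recall: 3.4
      spatial_span_backward: 2.5
      spatial_span_forward: 2.2
      trails_a_time: 30.0
      trails_b_time: 70.0
  group: AD
  severity_sd: 0.8
bvFTD:
  agent:
    latency_mu: 1.284
    latency_sd: 0.35
    rho_between: 0.89
    rho_within: 0.995
    sigma_scan: 0.2
  covariate_model:
    loadings:
      ace_total: -3.0
      ace_visuospatial: -0.4
      rcf_copy: -1.5
      rcf_copy_time: 25.0
      rcf_recall: 0.0
      spatial_span_backward: -0.6
      spatial_span_forward: -0.4
      trails_a_time: 15.0
      trails_b_time: 18.0
    means:
      ace_total: 74.0
      ace_visuospatial: 14.3
      rcf_copy: 26.2
      rcf_copy_time: 202.4
      rcf_recall: 8.3
      spatial_span_backward: 5.9
      spatial_span_forward: 6.4
      trails_a_time: 55.0
      trails_b_time: 135.0
    sds:
      ace_total: 11.7
      ace_visuospatial: 1.5
      rcf_copy: 7.2
      rcf_copy_time: 123.2
      rcf_recall: 6.8
      spatial_span_backward: 2.4
      spatial_span_forward: 2.1
      trails_a_time: 25.0
      trails_b_time: 60.0
  group: bvFTD
  severity_sd: 0.5
control:
  agent:
    latency_mu: 0.911
    latency_sd: 0.35
    rho_between: 0.9735
    rho_within: 0.995
    sigma_scan: 0.3
  covariate_model:
    loadings:
      ace_total: -1.0
      ace_visuospatial: -0.3
      rcf_copy: -1.0
      rcf_copy_time: 20.0
      rcf_recall: -1.5
      spatial_span_backward: -0.5
      spatial_span_forward: -0.4
      trails_a_time: 4.0
      trails_b_time: 8.0
    means:
      ace_total: 95.1
      ace_visuospatial: 15.4
      rcf_copy: 31.0
      rcf_copy_time: 182.5
      rcf_recall: 16.7
      spatial_span_backward: 7.5
      spatial_span_forward: 8.0
      trails_a_time: 36.0
      trails_b_time: 85.0
    sds:
      ace_total: 3.0
      ace_visuospatial: 0.9
      rcf_copy: 4.1
      rcf_copy_time: 68.7
      rcf_recall: 5.0
      spatial_span_backward: 1.8
      spatial_span_forward: 1.5
      trails_a_time: 12.0
      trails_b_time: 30.0
  group: control
  severity_sd: 0.25
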