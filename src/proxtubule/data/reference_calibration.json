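{
  "description": "Calibration record of the packaged reference epithelium: steady-state observables at 1 and 6 mM bilateral glucose versus their calibration targets.",
  "method": "bounded least squares on log-scaled free parameters (membrane permeabilities, hydraulic conductances, pump and carrier rate constants, compliance and impermeant content), weighted relative deviations",
  "targets": [
    {
      "observable": "jNa_pump_pmol_cm2_s",
      "bath_glucose_mM": 1.0,
      "target": 541.0,
      "fitted": 541.005102,
      "relative_residual": 9e-06
    },
    {
      "observable": "v_cell_mV",
      "bath_glucose_mM": 1.0,
      "target": -78.5,
      "fitted": -78.499592,
      "relative_residual": -5e-06
    },
    {
      "observable": "cGluc_cell_mM",
      "bath_glucose_mM": 1.0,
      "target": 1.88,
      "fitted": 1.879997,
      "relative_residual": -2e-06
    },
    {
      "observable": "cK_lis_mM",
      "bath_glucose_mM": 1.0,
      "target": 4.1,
      "fitted": 4.100097,
      "relative_residual": 2.4e-05
    },
    {
      "observable": "cNa_lis_mM",
      "bath_glucose_mM": 1.0,
      "target": 146.0,
      "fitted": 146.302994,
      "relative_residual": 0.002075
    },
    {
      "observable": "cGluc_lis_mM",
      "bath_glucose_mM": 1.0,
      "target": 0.91,
      "fitted": 1.002459,
      "relative_residual": 0.101603
    },
    {
      "observable": "vol_lis_nl_cm2",
      "bath_glucose_mM": 1.0,
      "target": 33.0,
      "fitted": 32.99902,
      "relative_residual": -3e-05
    },
    {
      "observable": "p_lis_excess_pa",
      "bath_glucose_mM": 1.0,
      "target": 75.0,
      "fitted": 74.99978,
      "relative_residual": -3e-06
    },
    {
      "observable": "jV_ibm_nl_cm2_s",
      "bath_glucose_mM": 1.0,
      "target": 4.9,
      "fitted": 4.900084,
      "relative_residual": 1.7e-05
    },
    {
      "observable": "jGluc_am_pmol_cm2_s",
      "bath_glucose_mM": 1.0,
      "target": 250.0,
      "fitted": 249.883858,
      "relative_residual": -0.000465
    },
    {
      "observable": "cCl_cell_mM",
      "bath_glucose_mM": 6.0,
      "target": 16.3,
      "fitted": 16.300144,
      "relative_residual": 9e-06
    },
    {
      "observable": "vol_cell_nl_cm2",
      "bath_glucose_mM": 6.0,
      "target": 1022.0,
      "fitted": 1021.999027,
      "relative_residual": -1e-06
    },
    {
      "observable": "absorbate_mosM",
      "bath_glucose_mM": 6.0,
      "target": 344.9,
      "fitted": 344.923213,
      "relative_residual": 6.7e-05
    },
    {
      "observable": "osm_lis_mosM",
      "bath_glucose_mM": 6.0,
      "target": 308.7,
      "fitted": 307.224851,
      "relative_residual": -0.004779
    },
    {
      "observable": "osm_cell_mosM",
      "bath_glucose_mM": 6.0,
      "target": 307.1,
      "fitted": 306.022219,
      "relative_residual": -0.00351
    }
  ]
}
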