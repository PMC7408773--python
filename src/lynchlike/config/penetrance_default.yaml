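# Replaceable age-banded cumulative-risk (penetrance) tables for the
# dominant two-class cosegregation model.  Values are plausible cumulative
# risks for a high-penetrance mismatch-repair predisposition allele versus
# general-population background; they are configuration, not calibration:
# swap in published gene-specific estimates for real analyses.
# Each vector gives the cumulative risk reached at the END of each age band.
age_bands:
  - [0, 20]
  - [20, 30]
  - [30, 40]
  - [40, 50]
  - [50, 60]
  - [60, 70]
  - [70, 80]
  - [80, 120]
risks:
  CRC:
    male:
      carrier:     [0.001, 0.010, 0.050, 0.120, 0.220, 0.330, 0.420, 0.460]
      non_carrier: [0.0001, 0.0003, 0.001, 0.004, 0.012, 0.025, 0.040, 0.050]
    female:
      carrier:     [0.001, 0.008, 0.040, 0.100, 0.180, 0.280, 0.360, 0.400]
      non_carrier: [0.0001, 0.0003, 0.001, 0.003, 0.009, 0.020, 0.033, 0.042]
  EC:
    female:
      carrier:     [0.000, 0.002, 0.020, 0.080, 0.180, 0.300, 0.380, 0.410]
      non_carrier: [0.000, 0.0002, 0.001, 0.004, 0.010, 0.018, 0.025, 0.030]
  OC:
    female:
      carrier:     [0.000, 0.001, 0.005, 0.020, 0.050, 0.080, 0.100, 0.110]
      non_carrier: [0.000, 0.0001, 0.0004, 0.002, 0.005, 0.008, 0.011, 0.013]
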