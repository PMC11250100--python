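{
  "version": "1",
  "features": [
    "amplitude_change_50ms",
    "mean_local_skew_15ms",
    "temporal_kurtosis",
    "amplitude_variance",
    "deriv_sum_50ms",
    "deriv_sum_100ms",
    "deriv_sum_200ms",
    "deriv_sum_300ms",
    "deriv_sum_500ms",
    "power_below_0p5hz",
    "bandpower_delta",
    "lambda_delta",
    "fiterror_delta",
    "bandpower_theta",
    "lambda_theta",
    "fiterror_theta",
    "bandpower_alpha",
    "lambda_alpha",
    "fiterror_alpha",
    "bandpower_beta",
    "lambda_beta",
    "fiterror_beta",
    "bandpower_gamma",
    "lambda_gamma",
    "fiterror_gamma",
    "bandpower_broadband",
    "lambda_broadband",
    "fiterror_broadband",
    "fd_kurtosis_higuchi",
    "fd_kurtosis_katz",
    "haar_kurtosis"
  ]
}
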