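{
  "deletion_length": {"family": "deletion_length", "method": "fixed", "n_bins": 5, "breaks": [3.0, 4.0, 4.7, 5.3], "log_transform": true, "degenerate": false},
  "duplication_length": {"family": "duplication_length", "method": "fixed", "n_bins": 5, "breaks": [3.0, 4.0, 4.7, 5.3], "log_transform": true, "degenerate": false},
  "deletion_magnitude": {"family": "deletion_magnitude", "method": "fixed", "n_bins": 3, "breaks": [-0.1, 0.1], "log_transform": false, "degenerate": false},
  "duplication_magnitude": {"family": "duplication_magnitude", "method": "fixed", "n_bins": 3, "breaks": [-0.1, 0.1], "log_transform": false, "degenerate": false},
  "segment_size": {"family": "segment_size", "method": "fixed", "n_bins": 3, "breaks": [6.0, 7.5], "log_transform": true, "degenerate": false},
  "segments_per_5mb": {"family": "segments_per_5mb", "method": "fixed", "n_bins": 3, "breaks": [2.5, 4.5], "log_transform": false, "degenerate": false},
  "oscillation_chain": {"family": "oscillation_chain", "method": "fixed", "n_bins": 3, "breaks": [3.5, 5.5], "log_transform": false, "degenerate": false},
  "segments_per_arm": {"family": "segments_per_arm", "method": "fixed", "n_bins": 3, "breaks": [1.5, 3.5], "log_transform": false, "degenerate": false},
  "changepoint": {"family": "changepoint", "method": "fixed", "n_bins": 5, "breaks": [0.75, 1.5, 2.5, 3.5], "log_transform": false, "degenerate": false}
}
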