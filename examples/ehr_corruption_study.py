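"""Synthetic-EHR corruption study at smoke scale (a few minutes on a laptop).

Generates a 300-patient synthetic ICU cohort (48-hour token streams, 17
concepts, imbalanced mortality driven by a latent severity), trains the
transformer ensemble (8 members) and the SNGP transformer pool (4 models),
corrupts the test episodes by random token replacement (RTR) and patient
token swapping (PTS) over d_proxy in {0.1, ..., 1.0}, and reports the share
of corrupted patients whose knowledge uncertainty stays below the
70th-percentile threshold.
"""

from kuq.pipeline import EhrRunConfig, run_ehr_experiment, comparison_table

cfg = EhrRunConfig(n_patients=300, smoke=True, seed=0)
reports = run_ehr_experiment(cfg)

print(comparison_table(list(reports.values())))
print("\nReading the table: 'rtr'/'pts' are the percentages of corrupted "
      "patients the estimator fails to flag at the 70th-percentile KU "
      "threshold. Random-input tokens (RTR) are glaring and well detected; "
      "swapped-in real tokens (PTS) are individually plausible and much "
      "harder; the SNGP leaves fewer of both undetected than the ensemble.")
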