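"""Generate a synthetic chronic low-back-pain cohort and inspect it.

Each patient gets a pain-site coordinate (cm from the top of the EMG
sheet), a pain-intensity NRS, 22 SF-MPQ-2 item scores, and a ground-truth
suppression fraction s in [0, 0.95) that drives how strongly muscle
activity is damped near the pain site in their experimental trials.
"""

import painmap
from painmap.cohort import patients_dataframe

config = painmap.CohortConfig(n_patients=6, n_trials=3, seed=1)
cohort = painmap.generate_cohort(config)

df = patients_dataframe(cohort.patients)
cols = ["patient_id", "pain_site_cm", "nrs", "neuropathic_pain", "total",
        "true_suppression"]
print(df[cols].round(3).to_string(index=False))
print(f"\nrecordings: {len(cohort.recordings)} "
      f"({config.n_patients} patients x (1 reference + {config.n_trials} trials))")
print("true_suppression is the generator's hidden effect size: the fraction of "
      "activity removed at the pain site itself; 0 means no motor adaptation.")
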