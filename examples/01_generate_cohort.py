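"""Generate a synthetic sepsis cohort with known SIC/DIC progression.

Each patient is an irregular laboratory event stream; the ground-truth
latent trajectory (SIC and overt-DIC onset hours) is returned alongside,
which real cohorts never provide — that is what makes every downstream
stage testable.
"""

import numpy as np

from coagcast import CohortConfig, generate_cohort, write_cohort

config = CohortConfig(n_patients=100, max_stay_h=120.0, seed=1)
streams, trajectories = generate_cohort(config)

sic = np.mean([t.ever_sic for t in trajectories])
dic = np.mean([t.ever_dic for t in trajectories])
events = np.mean([len(s.events) for s in streams])
print(f"patients:             {len(streams)}")
print(f"realized SIC / DIC:   {sic:.1%} / {dic:.1%}  (targets 37.1% / 17.8%)")
print(f"events per patient:   {events:.0f}")

p = next(t for t in trajectories if t.ever_dic)
print(f"example progression:  {p.patient_id} SIC at {p.sic_onset_h:.1f} h, "
      f"DIC at {p.dic_onset_h:.1f} h, stay {p.stay_h:.0f} h")

write_cohort(streams, "cohort.csv")
print("cohort written to cohort.csv (long format: patient_id, time_h, variable, value, unit)")
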