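"""Score a lab panel with the SIC and ISTH overt-DIC systems and build the
8 h window label timeline for one synthetic patient.

The two-step sequential rule means an assessment can only be DIC-positive
once SIC positivity has been reached at or before it.
"""

from coagcast import (CohortConfig, assess_stream, generate_cohort,
                      isth_dic_score, label_streams, sic_score)

res = sic_score(plt=90, inr=1.5, sofa=3)
print(f"SIC   plt=90 inr=1.5 sofa=3   -> subscores {res.subscores}, "
      f"total {res.total}, positive={res.positive}")
res = isth_dic_score(plt=40, fibrin_marker_value=6.0, pt_seconds=19.0,
                     fibrinogen_gL=0.8)
print(f"ISTH  plt=40 dd=6.0 pt=19 fib=0.8 -> subscores {res.subscores}, "
      f"total {res.total}, positive={res.positive}")

streams, trajs = generate_cohort(CohortConfig(n_patients=30, max_stay_h=120.0,
                                              seed=5))
timelines = label_streams(streams, stays={t.patient_id: t.stay_h for t in trajs})
patient = next(t for t in trajs if t.ever_dic)
tl = timelines[patient.patient_id]
print(f"\npatient {patient.patient_id}: true SIC onset {patient.sic_onset_h:.1f} h, "
      f"DIC onset {patient.dic_onset_h:.1f} h")
print("per-8h-window labels (sic, dic, provenance):")
for e in tl.labels:
    print(f"  window {e.window_index:2d} [{e.window_index * 8:5.1f} h)  "
          f"sic={e.sic_label}  dic={e.dic_label}  {e.provenance}")
n_assess = len(assess_stream(streams[[s.patient_id for s in streams]
                                     .index(patient.patient_id)]))
print(f"({n_assess} timestamped assessments were collapsed into "
      f"{tl.n_windows} windows)")
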