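"""Strict versus relaxed landmarking of a cohort at a landmark time.

Strict landmarking keeps only subjects still event-free at the landmark time
and truncates their longitudinal history there — in both training and test
data.  Relaxed landmarking (common in published pipelines) trains on full
follow-up of everyone and landmarks only the test data, which leaks
post-landmark information into the training model.
"""

import dynfpca as dp

study = dp.simulate_scenario(dp.scenario_config(2, n_subjects=400, seed=1))
data = study.dataset
t_lm = 6.0

strict = dp.strict_landmark(data, t_lm)
print(f"landmark {t_lm} y: {strict.n_subjects} of {data.n_subjects} subjects remain")
print(f"visits kept per subject: up to {len(strict.grid)} (grid truncated at {t_lm} y)")

train = data.subset(data.subject_ids[:300])
test = data.subset(data.subject_ids[300:])
train_view, test_view = dp.relaxed_landmark_views(train, test, t_lm)
print(f"relaxed training view: {train_view.n_subjects} subjects, full follow-up "
      f"(includes subjects with events before {t_lm} y)")
print(f"relaxed test view: {test_view.n_subjects} landmark survivors, history truncated")

plan = dp.make_fold_plan(data, "strict", t_lm, k=5, repeats=2, seed=0)
tr, te = plan.fold_ids(repeat=0, fold=0)
print(f"strict 5-fold plan: fold 0 has {len(tr)} training / {len(te)} test survivors")
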