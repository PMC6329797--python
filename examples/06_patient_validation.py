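"""Validate a cell-line-trained signature on a linked patient cohort.

Patients are simulated so that recurrence hazard depends on the same
planted genes; outcomes are binarized at an 18-month recurrence horizon
(resistant: recurrence by 18 months; sensitive: disease-free beyond it;
short-censored patients excluded) and the cell-line model is applied to
patient z-scores without retraining.
"""

import platinsig as ps

panel = ps.generate_panel(ps.PanelSpec(seed=1))
x = ps.zscore_normalize(panel.expression)
y = ps.label_by_threshold(panel.dose_response, panel.dose_response.median())
model = ps.train_svm(x, y, ps.SvmHyperparams(10.0, 10.0),
                     genes=panel.truth["informative_genes"])

cohort = ps.generate_cohort(
    ps.CohortSpec(n_patients=400, beta=2.0, seed=2,
                  covariate_effects={"smoking": -0.5}),
    panel.truth,
)
zc = ps.PatientCohort(ps.zscore_normalize(cohort.expression),
                      cohort.outcomes, cohort.covariates)

labeling = ps.label_outcomes(zc, recurrence_threshold=18.0)
pred = ps.predict_cohort(model, zc)
report = ps.evaluate(pred, labeling, strata=zc.covariates["smoking"])

print(f"patients: {report.n_sensitive} sensitive, {report.n_resistant} resistant, "
      f"{labeling.n_excluded} excluded (censored before 18 months)")
print(f"accuracy {report.accuracy:.3f} (sensitive {report.accuracy_sensitive:.3f}, "
      f"resistant {report.accuracy_resistant:.3f}), AUC {report.auc:.3f}")
for name, sub in report.per_stratum.items():
    print(f"  smoking={name}: accuracy {sub.accuracy:.3f}, AUC {sub.auc:.3f}")

kf = ps.kfold_patient_cv(model.genes, model.hyperparams, zc, labeling, k=5, seed=0)
print(f"5-fold patient-only CV (fixed genes/hyperparameters): accuracy {kf.accuracy:.3f}")
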