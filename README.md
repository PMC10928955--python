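# dynfpca

Dynamic prediction of survival probabilities from sparse longitudinal
biomarkers, for biostatisticians building or evaluating landmark-based
prediction models. The package implements a three-step pipeline:

1. **Landmarking.** At a landmark time *t*<sub>LM</sub>, predictions concern
   subjects still event-free. *Strict* landmarking removes subjects with an
   observed event or censoring before *t*<sub>LM</sub> and truncates the
   longitudinal history at *t*<sub>LM</sub> in **both** training and test
   data. *Relaxed* landmarking — the convention of several published
   pipelines — trains on everyone's full follow-up and landmarks only the
   test data, leaking post-landmark information into the model.
2. **Multivariate functional PCA.** Each longitudinal variable
   Y<sup>(q)</sup>(t) = X<sup>(q)</sup>(t) + ε is decomposed by the
   Karhunen–Loève expansion X<sup>(q)</sup>(t) = μ<sup>(q)</sup>(t) +
   Σ<sub>m</sub> ξ<sub>m</sub><sup>(q)</sup> φ<sub>m</sub><sup>(q)</sup>(t):
   penalized-spline mean, tensor-product-smoothed covariance surface with the
   noise-inflated diagonal excluded, eigendecomposition with
   proportion-of-variance (PVE) truncation, and conditional-expectation
   ("PACE") scores ξ̂ = λ̂ φ̂ᵀ Σ̂<sub>Y</sub><sup>−1</sup>(Y − μ̂) that remain
   well-defined for sparsely observed subjects. The Q univariate
   decompositions are combined into one multivariate decomposition (scores
   ρ̂<sub>im</sub>, eigenfunctions ψ̂<sub>m</sub>) through the one-to-one
   correspondence given by the eigenvectors of the stacked-score covariance.
   Optionally the mean is modelled on the *age-at-observation* scale,
   μ(t, a<sub>i</sub>) = μ(a<sub>i</sub> + t) ("age-based centring", ABC),
   removing the variation induced by age differences at study entry.
3. **Cox prediction.** A proportional-hazards model
   h(t | Z, ρ̂) = h₀(t) exp(βᵀZ + γᵀρ̂) fitted by Efron's partial likelihood
   (optionally with a LASSO penalty on the score coefficients γ only) with
   Breslow baseline hazard yields dynamic predictions
   π̂<sub>i</sub>(t | t<sub>LM</sub>) =
   (Ŝ₀(t)/Ŝ₀(t<sub>LM</sub>))<sup>exp(β̂ᵀZᵢ + γ̂ᵀρ̂ᵢ)</sup>.

Predictions are validated by IPCW time-dependent AUC and Brier score under
repeated k-fold cross-validation that honours the landmarking order (strict:
landmark first, then split; relaxed: split first, landmark the test fold
only). A full synthetic-study generator with a known subject-specific hazard
provides exact true conditional probabilities, so the mean squared error of
the predictions against the truth can be measured — the metric on which
strict landmarking clearly beats relaxed landmarking.

## Worked example

```python
import numpy as np
import dynfpca as dp

study = dp.simulate_scenario(dp.scenario_config(2, n_subjects=400, seed=1))
data, t_lm = study.dataset, 6.0

train = dp.strict_landmark(data.subset(data.subject_ids[:320]), t_lm)
test = dp.strict_landmark(data.subset(data.subject_ids[320:]), t_lm)

model, train_scores = dp.fit_mfpca(train, pve_target=0.95)
cox = dp.fit_cox(None, train_scores, train.time_observed, train.event, t_lm)
preds = dp.predict_survival(cox, None, dp.score_new_subjects(test, model),
                            np.arange(t_lm, 15.1, 0.5))
for t in (8.0, 10.0, 12.0):
    print(t, dp.td_auc(preds, test.time_observed, test.event, t),
          dp.mse_truth(preds, study.oracle, t))
```

prints (values from `examples/04_dynamic_prediction.py`):

```
t= 8.0: tdAUC 0.808  Brier 0.191  MSE vs truth 0.0083
t=10.0: tdAUC 0.816  Brier 0.167  MSE vs truth 0.0072
t=12.0: tdAUC 0.894  Brier 0.090  MSE vs truth 0.0111
```

tdAUC near 0.8–0.9 means the score summaries of the first six years of
trajectories discriminate well between subjects who fail early and late; the
MSE of ~0.01 means the predicted conditional survival probabilities sit
within about 0.1 of the exact simulated truth on average.

The `examples/` directory holds one short script per capability (simulation,
landmarking, mFPCA, dynamic prediction, cross-validated benchmarking);
`examples/05_strict_vs_relaxed_benchmark.py` reproduces the headline
comparison — strict landmarking recovers the true probabilities two to three
times more accurately (in MSE) than relaxed landmarking on the same data.

A thin command line mirrors the pipeline for shell use:

```sh
dynfpca simulate --scenario 2 --n 400 --seed 1 --out data/
dynfpca fit --long data/longitudinal.csv --baseline data/baseline.csv \
        --grid data/grid.csv --landmark-time 6 --out models/
dynfpca predict --long data/longitudinal.csv --baseline data/baseline.csv \
        --grid data/grid.csv --model-dir models/ --horizon 8,10,12 --out preds.csv
dynfpca evaluate --predictions preds.csv --baseline data/baseline.csv \
        --landmark-time 6 --out metrics.csv
```

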