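"""Full decoding chain on synthetic two-class trials.

Runs window -> filter bank -> covariances -> tangent features ->
MI-weighted fused-LASSO selection -> RBF-SVM under stratified 5-fold
cross-validation, once with well separated class covariances and once
with identical generating laws (where only chance accuracy is possible).
"""

from mipflasso import FilterBankSpec, PipelineConfig, TrialGenSpec, run_pipeline

fb = FilterBankSpec(bandwidths=(11.0,), f_lo=8.0, f_hi=30.0)

for sep in (3.0, 0.0):
    spec = TrialGenSpec(n_channels=8, n_trials_per_class=25, n_samples=500,
                        fs=250.0, class_sep=sep, noise_sd=0.5, seed=1)
    cfg = PipelineConfig(filter_bank=fb, n_folds=5, seed=1,
                         svm_C_grid=(1.0, 10.0))
    rep = run_pipeline(spec, cfg)
    sel = [f["n_selected"] for f in rep.per_fold]
    print(f"class_sep={sep}: accuracy {rep.mean['accuracy']:.2f} "
          f"+/- {rep.std['accuracy']:.2f}, F1 {rep.mean['f1']:.2f}, "
          f"G-mean {rep.mean['g_mean']:.2f}; "
          f"features kept per fold {sel} of {rep.per_fold[0]['n_features']}")
print("(separated covariances decode nearly perfectly; "
      "identical laws stay at chance)")
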