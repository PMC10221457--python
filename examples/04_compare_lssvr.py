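"""Head-to-head: sparse Bayesian MKRVR vs the dense LS-SVR baseline.

Both models share the same multi-kernel; LS-SVR solves one regularized
linear system and keeps every training point, while the relevance vector
machine prunes almost all of them.  The comparison is most interesting at
small training sizes.
"""

import numpy as np

from emgknee import (
    GaitSimConfig,
    MultiKernelSpec,
    build_dataset,
    evaluate,
    fit_lssvr,
    fit_rvr,
    generate_dataset,
    predict_lssvr,
    predict_rvr,
)

emg, markers, _ = generate_dataset(GaitSimConfig(n_cycles=30, seed=19))
dataset = build_dataset(emg, markers)
X_test, t_test = dataset.pooled(np.arange(20, 30))

print(f"{'train GCs':>9} | {'MKRVR MAE':>9} {'R2':>7} {'RVs':>4} | "
      f"{'LSSVR MAE':>9} {'R2':>7} {'SVs':>4}")
for n_train in (1, 5, 20):
    X, t = dataset.pooled(np.arange(n_train))
    rvr = fit_rvr(X, t, MultiKernelSpec())
    r1 = evaluate(t_test, predict_rvr(rvr, X_test)[0])
    svr = fit_lssvr(X, t, MultiKernelSpec(), reg_gamma=100.0)
    r2 = evaluate(t_test, predict_lssvr(svr, X_test))
    print(f"{n_train:>9} | {r1.mae:>9.2f} {r1.r2:>7.4f} "
          f"{rvr.n_relevance_vectors:>4} | {r2.mae:>9.2f} {r2.r2:>7.4f} "
          f"{svr.n_support_vectors:>4}")

print("\nMKRVR keeps a few relevance vectors (sparse, cheap to evaluate);")
print("LS-SVR keeps all N training points and trails at small sample sizes.")
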