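"""Train the GA-BP network and predict dose-volume parameters for a new tumor.

Scales the screened cohort (min-max features, percent outputs divided by
100), runs the genetic algorithm to choose initial weights/thresholds for
the 3-6-4 sigmoid network, refines them with online backpropagation
(eta = 0.1), and predicts whole-lung V5/V10/V20/V30 for a hypothetical
mid-lung tumor before any plan is made.
"""

import numpy as np

from dvhpredict import (
    CohortSpec,
    GAConfig,
    TrainConfig,
    apply_scaler,
    fit_scaler,
    ga_bp_train,
    generate_cohort,
    mahalanobis_filter,
    predict,
)

cohort = generate_cohort(CohortSpec(seed=1))
retained, _ = mahalanobis_filter(cohort, alpha=0.05)
scaler = fit_scaler(retained)
X, Y = apply_scaler(retained, scaler)

params, state = ga_bp_train(
    X, Y, GAConfig(seed=7), TrainConfig(max_epochs=300, shuffle_seed=7)
)
print(f"trained for {state.t} epochs; final training MSE {state.epoch_mse[-1]:.5f}")

new_tumor = np.array([[0.45, 0.70, 17.0]])  # P, L, S of a mid-lung tumor
v5, v10, v20, v30 = predict(params, scaler, new_tumor)[0]
print(f"predicted lung dose-volume parameters: "
      f"V5 {v5:.1f}%  V10 {v10:.1f}%  V20 {v20:.1f}%  V30 {v30:.1f}%")
print("These are pre-planning estimates a physicist can use as optimization goals.")
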