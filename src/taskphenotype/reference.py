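"""Published validation-study constants.

The battery was validated in two online studies; the second (n = 90,
all three tasks per participant) yielded fitted hierarchical-regression
models for PHQ-9 totals and descriptive moments for the behavioral
measures.  Those printed values are recorded here and serve as inputs
to the generative recovery simulations: data are simulated from the
fitted models and refit to check that the pipeline recovers the
published coefficients.
"""

from __future__ import annotations

# ---- Study-Two cohort demographics -------------------------------------
STUDY2_N = 90
STUDY2_MALE_PROPORTION = 57 / 90  # 57 male, 33 female
STUDY2_AGE_MEAN = 37.944
STUDY2_AGE_SD = 11.155

# ---- Study-Two descriptive moments (mean, SD) per measure ---------------
STUDY2_METRIC_MOMENTS: dict[str, tuple[float, float]] = {
    "phq9_total": (7.022, 6.892),
    "d2_n_items": (419.233, 94.922),
    "d2_n_correct": (168.133, 43.076),
    "d2_n_omission": (22.211, 22.142),
    "d2_n_commission": (20.600, 37.195),
    "d2_n_errors": (42.811, 52.897),
    "d2_error_rate": (10.244, 11.217),
    "dmts_n_correct": (31.700, 6.523),
    "dmts_avg_latency_ms": (4128.393, 6994.663),
    "dmts_n_color_errors": (1.933, 2.508),
    "dmts_n_shape_errors": (4.767, 3.006),
    "dmts_n_both_errors": (1.600, 2.350),
    "swm_n_between_errors": (92.278, 55.287),
    "swm_n_within_errors": (19.822, 38.204),
    "swm_strategy_score": (40.511, 8.260),
}

# ---- Fitted demographics-only (null) model ------------------------------
# PHQ-9 ~ intercept + age + gender(male=1); R2 = 0.083, F(2, 87) = 3.944
NULL_MODEL_COEF: dict[str, float] = {
    "intercept": 13.966,
    "age": -0.180,
    "gender": -0.487,
}
NULL_MODEL_RESIDUAL_SD = 6.6
NULL_MODEL_R2 = 0.083
NULL_MODEL_F = 3.944

# ---- Fitted combined model (demographics + one metric per task) ---------
# Second block adds D2 total errors, DMTS correct choices, SWM within
# errors; R2 = 0.344, F(5, 84) = 8.799, dR2 = 0.261, dF(3, 84) = 11.119
COMBINED_MODEL_COEF: dict[str, float] = {
    "intercept": 16.176,
    "age": -0.069,
    "gender": -0.649,
    "d2_n_errors": 0.035,
    "dmts_n_correct": -0.272,
    "swm_n_within_errors": 0.038,
}
COMBINED_MODEL_RESIDUAL_SD = 5.6
COMBINED_MODEL_R2 = 0.344
COMBINED_MODEL_F = 8.799
COMBINED_MODEL_DELTA_R2 = 0.261
COMBINED_MODEL_DELTA_F = 11.119

#: predictor moments for the combined-model recovery simulation
COMBINED_MODEL_PREDICTOR_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (STUDY2_AGE_MEAN, STUDY2_AGE_SD),
    "d2_n_errors": STUDY2_METRIC_MOMENTS["d2_n_errors"],
    "dmts_n_correct": STUDY2_METRIC_MOMENTS["dmts_n_correct"],
    "swm_n_within_errors": STUDY2_METRIC_MOMENTS["swm_n_within_errors"],
}
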