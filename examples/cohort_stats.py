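"""Synthetic cohort end-to-end: group comparison with blocked CV.

Generates a professional-like group (strong anti-phase attractor) and an
amateur-like group (weak attractor, same noise intensity), analyses every
trial, and tests the group effect on each metric with a linear mixed
model (random intercepts for participant and trial) plus repeated
blocked 5-fold cross-validation.
"""

from tapdyn.pipeline import PipelineConfig, run_cohort

config = PipelineConfig(participants_per_group=8, trials_per_participant=3,
                        master_seed=0, cv_reps=2000, cv_seed=0)
result = run_cohort(config)

print(f"{len(result.table)} trials analysed "
      f"({result.manifest['n_trials_excluded']} excluded)")
print(result.table.groupby("group")[["lrv", "percent_rec", "lmax"]]
      .mean().round(3))
print()
for resp in ("lrv", "percent_rec", "lmax"):
    lm = result.lmm[resp]
    cv = result.cv[resp]
    sig = "significant" if lm.p_value < 0.05 else "not significant"
    print(f"{resp:12s}: beta = {lm.beta:8.3f}  chi2(1) = {lm.wald_chisq:6.2f}  "
          f"p = {lm.p_value:.4f} ({sig})  eta_p2 = {lm.partial_eta_sq:.2f}  "
          f"CV wins {cv.model2_wins}/{cv.reps}")
print()
print("Expected pattern: the groups separate on LRV (phase consistency) "
      "and Lmax (attractor strength) but not on %REC, because both "
      "presets share the same noise intensity Q.")
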