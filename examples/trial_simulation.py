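"""Round a continuous design to 40 patients and simulate its performance.

Takes the restricted c-optimal design, apportions the weights into
integer patient counts by efficient rounding, then runs a Monte Carlo
study: each replicate simulates trinomial outcomes for all 40 patients,
refits the model by maximum likelihood, and re-estimates the MTD and
OBD.  Bias/SD/RMSE summarise how well a 40-patient trial run under this
design would pin down the two target doses.
"""

from crdesign import (
    ContinuousDesign,
    CRParams,
    DoseInterval,
    operating_characteristics,
    round_design,
)

params = CRParams(-6.0, 0.72, -3.5, 1.0)
interval = DoseInterval(0.0, 10.0)
design = ContinuousDesign([3.61, 6.41], [0.376, 0.624])

exact = round_design(design, 40)
print("allocation:", ", ".join(f"{c} patients at dose {d:.2f}"
                               for d, c in zip(exact.doses, exact.counts)))

oc = operating_characteristics(
    design, params, gamma=0.2, interval=interval, n=40, n_reps=500, seed=11
)
print(f"\nover {oc.n_reps} simulated trials ({oc.n_determined} with a usable fit):")
print(f"  MTD estimator: bias {oc.mtd_bias:+.3f}, SD {oc.mtd_sd:.3f}, RMSE {oc.mtd_rmse:.3f}")
print(f"  OBD estimator: bias {oc.obd_bias:+.3f}, SD {oc.obd_sd:.3f}, RMSE {oc.obd_rmse:.3f}")
print(f"  Pr(undetermined MLE): {oc.pr_no_mle:.3f}")
print(
    "\nRMSE is in dose units; an RMSE near 1 means a typical 40-patient\n"
    "trial misses the target dose by about one dose unit.  Replicates\n"
    "whose likelihood fit separates (no finite MLE) are excluded from the\n"
    "error summaries and counted in Pr(undetermined MLE)."
)
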