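"""Dose-response curves, MTD and OBD of a continuation-ratio model.

Builds the worked-example model (toxicity logistic intercept -6, slope
0.72; conditional-efficacy intercept -3.5, slope 1) and prints the two
doses a phase I/II trial targets: the maximum tolerated dose (toxicity
probability = 20%) and the optimal biological dose (maximising efficacy
without toxicity over the study range [0, 10]).
"""

import numpy as np

from crdesign import CRParams, DoseInterval, mtd, obd, outcome_probabilities

params = CRParams(alpha_tox=-6.0, beta_tox=0.72, alpha_eff=-3.5, beta_eff=1.0)
interval = DoseInterval(0.0, 10.0)

print("dose   P(no eff, no tox)  P(eff, no tox)  P(tox)")
for d in np.arange(0.0, 10.5, 2.0):
    p = outcome_probabilities(d, params)
    print(f"{d:4.1f}   {p.p_none:15.3f}  {p.p_eff:14.3f}  {p.p_tox:6.3f}")

print(f"\nMTD (20% toxicity):            {mtd(params, 0.2):.2f}")
print(f"OBD (max efficacy w/o tox):    {obd(params, interval):.2f}")
print(
    "\nThe OBD sits just below the MTD here: efficacy-without-toxicity peaks\n"
    "where the rising efficacy curve is overtaken by rising toxicity."
)
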