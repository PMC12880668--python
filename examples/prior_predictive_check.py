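"""Prior-predictive check: do the default priors span physiological glucose?

Draws full hierarchies from the prior, simulates the packaged exemplary day
under each draw, and reports (a) how much of the simulated trajectory mass
stays inside the physiological 0-400 mg/dL band and (b) the terminal
glucose distribution when conditioning on zero insulin and zero meals,
which should approach the renal-excretion-limited plateau near 400 mg/dL.
"""

import numpy as np

from glucotwin import build_priors, exemplary_day, prior_predictive

pp = prior_predictive(build_priors(), exemplary_day(), n=200, seed=3)

q = np.percentile(pp["G"], [5, 50, 95])
print(f"simulated glucose percentiles (5/50/95): {q[0]:.0f} / {q[1]:.0f} / {q[2]:.0f} mg/dL")
print(f"fraction of trajectory-minutes in [0, 400] mg/dL: {pp['frac_in_range']:.3f}")
print(f"zero-insulin terminal glucose, median: {pp['median_terminal_zero_insulin']:.0f} mg/dL")
# The first number should be >= 0.95 (priors cover, but do not overflow,
# the physiological range); the second should exceed 300 mg/dL — without
# insulin, production balances clearance only once renal excretion is
# strongly active.
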