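"""Measure gait robustness: the largest survivable one-time perturbation.

Starting from the stable gait, a one-time floor-height change is applied
at the first foot strike and the walker must complete 30 further steps.
Geometric bracketing plus bisection finds the largest step-up and
step-down the gait survives; their sum is the height robustness.
"""

from compassgait import (WalkerParams, cold_start_guess, find_period_one,
                         make_model, robustness)

params = WalkerParams(beta=0.01, gamma=0.009)
model = make_model("point_el", params)
sol = find_period_one(model, cold_start_guess("point_el", params))

res = robustness(model, sol.fixed_state, kinds=("step_height",))
print(f"max step-up   = {res.max_step_up:.5f} leg lengths")
print(f"max step-down = {res.max_step_down:.5f} leg lengths")
print(f"height robustness (sum) = {res.robustness_height:.5f}")
print()
print("A few millimeters per meter of leg: passive point-feet walkers are")
print("fragile, which is what makes predicting their robustness from")
print("stability measures a sharp test.")
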