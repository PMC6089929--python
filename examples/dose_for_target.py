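"""Choose a daily dose that reaches a target steady-state INR.

Inverts the steady-state INR prediction: given a patient's sensitivity
ratio (D_ref/D from a previous prediction) and a target INR, find the dose
whose predicted steady-state INR equals the target.
"""

from warfinr import dose_for_target_inr, steady_state_inr

# A typical patient (sensitivity ratio 1) aiming at the middle of the
# usual therapeutic range, INR 2.5:
for ratio, label in [(1.0, "typical patient"), (1.5, "warfarin-sensitive patient")]:
    dose = dose_for_target_inr(target_inr=2.5, sensitivity_ratio=ratio, inr0=1.0)
    check = steady_state_inr(ratio * dose, 1.0)
    print(f"{label} (D_ref/D = {ratio}):")
    print(f"  dose for INR_SS = 2.5: {dose:.2f} mg/day (check: INR_SS = {check:.2f})")

# The sensitive patient needs a proportionally lower dose: their response
# matches a typical patient taking ratio-times their dose.
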