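"""Predict time to steady-state INR and steady-state INR for one patient.

Input: two timed, paired measurements of INR and factor VII (% of the
pre-treatment baseline) drawn on days 3 and 4 after starting warfarin
5 mg/day. Output: the individualised reference dose D_ref, the predicted
time to steady-state INR, and the predicted steady-state INR.
"""

from warfinr import DoseContext, PairedSample, predict

# Day-3 / day-4 paired samples for a patient on 5 mg/day.
s1 = PairedSample(t=3.0, inr=2.575, vii=50.0)
s2 = PairedSample(t=4.0, inr=3.591, vii=50.0)

result = predict(s1, s2, DoseContext(dose=5.0, inr0=1.0))

print(f"SI_VII at day 3:          {result.si_t1:.5f} per %")
print(f"SI_VII at day 4:          {result.si_t2:.5f} per %")
print(f"dSI_VII/dt:               {result.slope:.5f} per %/day")
print(f"D_ref:                    {result.dref:.2f} mg/day")
print(f"sensitivity ratio D_ref/D: {result.sensitivity_ratio:.2f}")
print(f"t_SS,INR:                 {result.t_ss_inr:.1f} days")
print(f"INR_SS:                   {result.inr_ss:.2f}")
for w in result.warnings:
    print("warning:", w)

# D_ref above the given 5 mg/day means this patient responds like a typical
# patient on a higher dose, i.e. is more sensitive to warfarin; the INR will
# keep drifting up until t_SS,INR, so an INR measured before then
# underestimates the eventual steady-state INR.
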