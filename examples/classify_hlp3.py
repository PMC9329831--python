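"""Screen patients for dysbetalipoproteinemia (HLP3) by every rule.

Three rules that need no ultracentrifuge are compared on two patients: the
estimated-ratio screens (standard-panel estimate at cut-point 0.194,
apoB-enhanced estimate at 0.209) and the dual apoB ratio rule
(TC/apoB >= 6.2 and TG/apoB <= 10 in SI units).
"""

from vldlc import LipidPanel, dual_apob_call, estimated_ratio_call

patients = {
    "suspected HLP3": LipidPanel(tc=340, hdl_c=40, tg=375, apob=118),
    "common mixed dyslipidemia": LipidPanel(tc=194, hdl_c=47, tg=164, apob=99),
}

for name, panel in patients.items():
    print(f"{name}: TC {panel.tc} HDL-C {panel.hdl_c} TG {panel.tg} apoB {panel.apob}")
    for method in ("s_ratio", "es_ratio"):
        call = estimated_ratio_call(panel, method)
        print(f"  {method:>9}: {call.status:8}  score {call.score:.3f} "
              f"vs cut-point {call.cutpoint}")
    dual = dual_apob_call(panel.tc, panel.tg, panel.apob)
    print(f"  dual_apob: {dual.status:8}  TC/apoB {dual.score:.2f} (SI)")
print("The score is the estimated VLDL-C divided by plasma TG; a call is"
      " positive when it reaches the method's cut-point with TG inside the"
      " 150-1000 mg/dL window.")
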