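"""Screen clinical variables against the tumor outcome with bias-corrected
Cramér's V.

The plain V statistic is upward biased on finite samples; the corrected
variant subtracts the chance-level expectation, so weakly associated
variables fall toward zero while genuinely associated ones (here planted at
V = 0.41 and 0.38) stay high.
"""

from radsignet import SimConfig, associate_clinical, generate_cohort

cohort = generate_cohort(SimConfig(seed=7).scaled(0.05))
report = associate_clinical(cohort.clinical, cohort.labels)
print(report.to_string(index=False))
print()
print("The generator plants corrected-V targets of 0.41 (symptoms) and 0.38")
print("(tumor size, gross adjacent involvement); every other variable is")
print("weak (0.1). At n=145 the estimates scatter around those targets, and")
print("v_corrected <= v on every row — the correction removes chance-level")
print("association.")
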