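"""Score a simulated 3D-spheroid dose response with DSS1/2/3.

Builds a raw-signal viability plate for one compound (vehicle wells = 100%
sphere formation, benzethonium-style kill wells = 0%), normalizes it,
converts to % inhibition, fits the 4PL curve and computes the drug
sensitivity scores over the 0.6-40 uM screening window.
"""

import numpy as np

from covscreen import dss, fit_logistic4, normalize_viability, percent_inhibition
from covscreen.plate_core import average_replicates
from covscreen.synthetic import SimulationConfig, gen_dose_response

# ground truth: 85% max inhibition, Hill 1.2, midpoint 8 uM; 2% CV noise
cfg = SimulationConfig(seed=11, cv=0.02, additive_frac=0.002, replicates=3)
plate = gen_dose_response(0.0, 85.0, 1.2, np.log10(8e-6), cfg)

resp = average_replicates(percent_inhibition(normalize_viability(plate)))
treated = resp[resp["conc"] > 0]
fit = fit_logistic4(treated["conc"].to_numpy(), treated["value"].to_numpy())
res = dss(fit, cmin=np.log10(0.6e-6), cmax=np.log10(40e-6), t=10.0)

print(f"fitted IC50      : {fit.ic50 * 1e6:.2f} uM (truth 8.00)")
print(f"top asymptote a  : {res.a:.1f} %")
print(f"DSS1 / DSS2 / DSS3: {res.dss1:.1f} / {res.dss2:.1f} / {res.dss3:.1f}")
print()
print("DSS1 is the threshold-corrected normalized area under the % inhibition")
print("curve; DSS2 discounts a sub-100% asymptote; DSS3 additionally down-")
print("weights activity confined to a narrow top-dose window. Higher = more potent.")
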