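"""Downstream biochemical quantitation: rates, 4PL fits, stoichiometry, ΔΔCt.

Walks through the assay toolbox on synthetic data with known answers:
a DiFMU standard-curve rate conversion, an enzyme-activation dose–response
fit (EC50 and Vmax), intact-MS labeling stoichiometry, an ELISA standard
curve with intrapolated unknowns, and qPCR ΔΔCt fold changes.
"""

import numpy as np
import pandas as pd

from cysredox import assays
from cysredox.synth import (
    SyntheticConfig,
    gen_activity_doseresponse,
    gen_intactms_species,
    gen_kinetic_trace,
)

cfg = SyntheticConfig(seed=3)

# -- kinetic rate via DiFMU standard curve (1 pmol DiFMU = 1 pmol phosphate)
pmol = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
curve = assays.fit_difmu_standard(pmol, 2.0 * pmol + 1.0)
trace = gen_kinetic_trace(cfg, rate_pmol_min=7.0, au_per_pmol=2.0, noise_sd_au=0.5)
rate = assays.difmu_rate(trace["time_min"], trace["fluorescence"], curve)
print(f"phosphatase rate: {rate:.2f} pmol phosphate/min (simulated at 7.00)")

# -- activation dose-response: EC50 / Vmax
dr, truth = gen_activity_doseresponse(cfg, noise_cv=0.02, n_replicates=4)
fit = assays.fit_4pl(dr["dose_uM"], dr["response"], direction="activation")
print(f"activation fit: EC50 {fit.ec50:.1f} uM, Vmax {fit.vmax:.1f} pmol/min, "
      f"hill {fit.params.hill:.2f} (truth: EC50 {truth.ec50}, Vmax {truth.top})")

# -- intact-MS stoichiometry
species = gen_intactms_species([0.2, 0.8])
pct = assays.intact_percent_engagement(species)
print(f"intact-MS engagement: {pct:.0f}% of molecules carry >=1 adduct")

# -- ELISA standard curve + intrapolation
std_conc = np.geomspace(7.8, 4000, 8)  # pg/ml
std_truth = assays.FourPL(bottom=0.05, top=3.0, ec50=200.0, hill=1.2)
elisa = assays.fit_elisa_standard(std_conc, std_truth(std_conc))
unknown = assays.elisa_intrapolate(elisa, std_truth(np.array([150.0])))
print(f"ELISA unknown: {unknown[0]['concentration']:.0f} pg/ml (planted 150)")

# -- qPCR ΔΔCt
ct = pd.DataFrame(
    [("GAPDH", "dmso", 18.0), ("GAPDH", "treated", 18.5),
     ("IL6", "dmso", 25.0), ("IL6", "treated", 24.5)],
    columns=["gene", "sample", "ct"],
)
fc = assays.ddct_fold_change(ct, reference_gene="GAPDH", calibrator_sample="dmso")
print("IL6 fold change vs DMSO:",
      float(fc.query("gene == 'IL6' and sample == 'treated'")["fold_change"].iloc[0]))
# A ΔΔCt of −1 doubles expression; the activation fit's top is the maximal
# rate (Vmax) and its midpoint dose the EC50.
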