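"""Quantify prepulse inhibition from a trial table.

A weak prepulse suppresses the response to a strong stimulus that
follows it; %PPI compares response frequency on prepulse trials with
interleaved isolated-stimulus controls.  Fish that respond to the
prepulse itself are excluded.
"""

import numpy as np

from zfplate import ppi_analysis
from zfplate.assays import PpiTrial

rng = np.random.default_rng(0)
trials = []
for grp, p_ctrl, p_ppi in [("sibling", 0.8, 0.35), ("mutant", 0.8, 0.65)]:
    for fish in range(30):
        for k in range(6):
            trials.append(PpiTrial(f"f{fish}", grp, "control",
                                   bool(rng.random() < p_ctrl)))
            trials.append(PpiTrial(
                f"f{fish}", grp, "ppi", bool(rng.random() < p_ppi),
                prepulse_responded=bool(rng.random() < 0.04)))

for grp, res in ppi_analysis(trials).items():
    print(f"{grp:8s} control {res.p_control:.2f}  ppi {res.p_ppi:.2f}  "
          f"%PPI {res.ppi_percent:5.1f}  "
          f"(excluded {res.n_excluded} prepulse-responding trials)")
# Reduced %PPI in the mutant is the sensorimotor-gating deficit
# phenotype: the prepulse fails to suppress its startle.
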