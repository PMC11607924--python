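"""The full four-model calibration study on one synthetic dataset.

Runs every shipped preset (PLS, ANN, SVR, GBT × PIO, ALG, GLM) through band
selection, preprocessing, optional score compression, fitting and test-set
evaluation, then ranks the models per analyte.
"""

import numpy as np

import mixcal
from mixcal.evaluate import report_to_frame

cfg = mixcal.preset_study_config(seed=1)
report = mixcal.run_pipeline(cfg)

df = report_to_frame(report)
print(df.round(3).to_string(index=False))
print(f"\nconfig hash {report['config_hash']}, seed {report['seed']}")
print("""
Reading the table: RMSEP is the test-set error in µg/mL, recovery the
predicted/nominal ratio in %, RPD = sd(reference)/RMSEP (higher is better),
R² the fraction of test-set variance explained.  On mild-noise, zero-
saturation mixtures every preset recovers the two major analytes within
~2 %; the GLM column shows why the minor component is the hard problem —
its high-gamma SVR preset collapses on spectra it was not calibrated for,
mirroring the matrix-sensitivity such narrow kernels have in practice.""")
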