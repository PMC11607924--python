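"""SIMPLS calibration with leave-one-out latent-variable selection.

Fits PLS1 per analyte on the 25 calibration mixtures, picks the number of
latent variables by the fewest-components PRESS rule, and evaluates
recovery on the 12 independent test mixtures.
"""

import numpy as np

import mixcal
from mixcal.preprocess import ANALYTE_BANDS, select_bands

design = mixcal.load_table1_fixture()
cfg = mixcal.DistortionConfig(noise_sd=0.002, seed=11)
spectra, conc = mixcal.simulate_dataset(design, cfg=cfg)
ids_m = list(design.sets.index[design.sets == "M"])
ids_t = list(design.sets.index[design.sets == "T"])

for analyte in ("PIO", "ALG", "GLM"):
    banded = select_bands(spectra, ANALYTE_BANDS[analyte])
    y_m = conc.loc[ids_m, analyte].to_numpy()
    y_t = conc.loc[ids_t, analyte].to_numpy()
    model = mixcal.fit_with_cv(banded.subset(ids_m), y_m, max_lv=8)
    pred = mixcal.pls_predict(model, banded.subset(ids_t))
    rec = mixcal.metrics(pred, y_t)
    print(f"{analyte}: {model.n_lv} LVs "
          f"(RMSECV {model.rmsecv[model.n_lv - 1]:.4f}), "
          f"test RMSEP {rec.rmsep:.4f} µg/mL, "
          f"mean recovery {rec.mean_recovery:.2f} ± {rec.sd_recovery:.2f} %")

print("\nThree latent variables per analyte — one per absorbing species —")
print("is what the PRESS curve should find on near-linear mixtures;")
print("recoveries near 100 % show the design + bands carry enough information.")
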