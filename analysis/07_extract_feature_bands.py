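#!/usr/bin/env python
"""Extract spectral biomarker bands from the top PLSDA loadings.

Reports the prominent extrema of the LV1 (and LV2, if present) loadings
with their signs - the wavenumbers that drive the HK-vs-OSCC
discrimination. On the synthetic cohort these should land on the
generator's class-differential band centers (amide I/II, amide III,
phosphate, carbohydrate and DNA-backbone bands).
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oralftir import RunConfig, io
from oralftir.evaluation import venetian_blinds
from oralftir.plsda import extract_feature_bands, feature_bands_frame, fit_plsda, select_n_lv
from oralftir.preprocessing import second_derivative

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    config = RunConfig(seed=42)
    reps = io.read_csv_spectra(SCRATCH / "representatives.csv")
    model_input = second_derivative(reps, config.preprocess)
    train = model_input.select_rows(np.isin(model_input.classes, ("H", "C")))
    folds = venetian_blinds(train, k=config.cv_k)
    n_lv, _, _ = select_n_lv(train, train.classes, folds.folds, config.max_lv)
    model = fit_plsda(train, train.classes, n_lv=n_lv, threshold=config.threshold)

    bands = extract_feature_bands(model, lv_indices=sorted({1, min(2, model.n_lv)}))
    table = feature_bands_frame(bands)
    table.to_csv(RESULTS / "feature_bands.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"wrote {RESULTS / 'feature_bands.csv'}")


if __name__ == "__main__":
    main()
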