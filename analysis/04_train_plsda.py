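#!/usr/bin/env python
"""Train the HK-vs-OSCC PLSDA model on second-derivative representatives.

Loads the representative spectra written by 03_pixel_qc.py, applies the
7-point second derivative with renormalization, selects the latent-variable
count by grouped venetian-blinds CV error, and fits the final model.
Writes the LV error curves and per-LV explained X-variance.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oralftir import RunConfig, io
from oralftir.evaluation import venetian_blinds
from oralftir.plsda import fit_plsda, select_n_lv
from oralftir.preprocessing import second_derivative

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    config = RunConfig(seed=42)
    reps = io.read_csv_spectra(SCRATCH / "representatives.csv")
    model_input = second_derivative(reps, config.preprocess)

    train = model_input.select_rows(np.isin(model_input.classes, ("H", "C")))
    folds = venetian_blinds(train, k=config.cv_k)
    n_lv, cal_err, cv_err = select_n_lv(train, train.classes, folds.folds, config.max_lv)
    model = fit_plsda(train, train.classes, n_lv=n_lv, threshold=config.threshold)

    curves = pd.DataFrame(
        {
            "n_lv": np.arange(1, len(cv_err) + 1),
            "calibration_error": cal_err,
            "cv_error": cv_err,
        }
    )
    curves.to_csv(RESULTS / "lv_error_curves.csv", index=False)
    pd.DataFrame(
        {
            "lv": np.arange(1, model.n_lv + 1),
            "explained_x_variance_pct": model.explained_x_variance,
        }
    ).to_csv(RESULTS / "explained_variance.csv", index=False)

    print(f"trained on {train.n_spectra} spectra "
          f"({(train.classes == 'H').sum()} H, {(train.classes == 'C').sum()} C)")
    print(f"selected {n_lv} latent variable(s); CV error curve: {np.round(cv_err, 3)}")
    print("explained X-variance per LV (%):",
          np.round(model.explained_x_variance, 2))
    print(f"wrote {RESULTS / 'lv_error_curves.csv'} and {RESULTS / 'explained_variance.csv'}")


if __name__ == "__main__":
    main()
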