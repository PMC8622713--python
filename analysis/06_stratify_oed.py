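#!/usr/bin/env python
"""Grade the dysplasia samples by which side of the PLSDA line they fall on.

Applies the trained HK-vs-OSCC model to the 22 dysplasia representative
spectra: a sample with both scores below 0.5 is HK-grade, both above is
OSCC-grade, and a pair straddling the line is borderline. Writes the
per-sample table and a score plot (scratch/figures/).
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oralftir import RunConfig, io
from oralftir.evaluation import venetian_blinds
from oralftir.plsda import fit_plsda, select_n_lv
from oralftir.preprocessing import second_derivative
from oralftir.stratify import stratification_report, stratify

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
FIGURES = Path(__file__).resolve().parents[1] / "scratch" / "figures"


def main() -> None:
    config = RunConfig(seed=42)
    reps = io.read_csv_spectra(SCRATCH / "representatives.csv")
    model_input = second_derivative(reps, config.preprocess)
    train = model_input.select_rows(np.isin(model_input.classes, ("H", "C")))
    folds = venetian_blinds(train, k=config.cv_k)
    n_lv, _, _ = select_n_lv(train, train.classes, folds.folds, config.max_lv)
    model = fit_plsda(train, train.classes, n_lv=n_lv, threshold=config.threshold)

    oed = model_input.select_rows(model_input.classes == "D")
    result = stratify(model, oed, delta=config.delta)
    table = stratification_report(result)
    table.to_csv(RESULTS / "oed_stratification.csv", index=False)
    io.write_json(result.to_dict(), RESULTS / "oed_stratification.json")

    FIGURES.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"HK-grade": "tab:green", "OSCC-grade": "tab:red", "borderline": "tab:purple"}
    for i, rec in enumerate(table.itertuples(index=False)):
        ax.plot([i, i], [rec.score_1, rec.score_2], "-", color=colors[rec.grade], lw=1.5)
        ax.plot([i, i], [rec.score_1, rec.score_2], "o", color=colors[rec.grade], ms=5)
    ax.axhline(model.threshold, ls="--", color="purple", lw=1, label="discrimination line")
    ax.set_xticks(range(len(table)), table["sample_id"], rotation=45)
    ax.set_ylabel("PLSDA predicted score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIGURES / "oed_score_plot.png", dpi=150)

    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\ngrade counts: {result.grade_counts}")
    print(f"wrote {RESULTS / 'oed_stratification.csv'} and {FIGURES / 'oed_score_plot.png'}")


if __name__ == "__main__":
    main()
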