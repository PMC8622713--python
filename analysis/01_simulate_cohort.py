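#!/usr/bin/env python
"""Generate the default synthetic biopsy cohort and summarize it.

The design mirrors the study this pipeline targets: 12 hyperkeratosis (H),
11 dysplasia (D) and 11 carcinoma (C) samples, each imaged over several
16x16-pixel areas; dysplasia samples carry a latent grade (6 HK-like,
4 OSCC-like, 1 borderline) that later stages try to recover. Writes the
sample table with ground truth to results/ and one example ENVI cube to
scratch/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oralftir import RunConfig, io
from oralftir.pipeline import stage_simulate

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    config = RunConfig(seed=42)
    cohort = stage_simulate(config)

    RESULTS.mkdir(exist_ok=True)
    cohort.samples.to_csv(RESULTS / "cohort_samples.csv", index=False)

    tissue_counts = cohort.pixels.meta["tissue"].value_counts().to_dict()
    summary = {
        "n_samples": int(cohort.samples.shape[0]),
        "n_areas": len(cohort.areas),
        "n_pixel_spectra": cohort.pixels.n_spectra,
        "tissue_counts": {k: int(v) for k, v in tissue_counts.items()},
        "class_counts": {
            k: int(v) for k, v in cohort.samples["class_label"].value_counts().items()
        },
    }
    io.write_json(summary, RESULTS / "cohort_summary.json")

    cube_dir = SCRATCH / "cubes"
    cube_dir.mkdir(parents=True, exist_ok=True)
    first_area = cohort.pixels.select_rows(
        (cohort.pixels.meta["area_id"] == cohort.areas[0]).to_numpy()
    )
    io.write_envi_cube(first_area, cube_dir / f"{cohort.areas[0]}.raw")

    print(f"simulated {summary['n_samples']} samples "
          f"({summary['class_counts']}) over {summary['n_areas']} areas")
    print(f"pixel spectra: {summary['n_pixel_spectra']}; "
          f"tissue ground truth: {summary['tissue_counts']}")
    print(f"wrote {RESULTS / 'cohort_samples.csv'} and an example cube under {cube_dir}")


if __name__ == "__main__":
    main()
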