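"""Grading dysplasia samples by spectral similarity to HK or OSCC.

The trained HK-vs-OSCC model scores each dysplasia (OED) sample's two
representative spectra; the sample is graded by which side of the 0.5
discrimination line the pair falls on: both at or below ``threshold -
delta`` -> HK-grade, both at or above ``threshold + delta`` -> OSCC-grade,
anything else (the pair straddles the line, or a score sits inside the
``delta`` band) -> borderline. With the default ``delta = 0`` the rule is
purely side-based; a pair sitting exactly on the line resolves to
OSCC-grade, consistent with the classifier's tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpectrumSet
from .plsda import PLSDAModel

GRADES = ("HK-grade", "OSCC-grade", "borderline")


@dataclass
class StratificationResult:
    """Per-sample grades with the scores that justify them."""

    table: pd.DataFrame  # sample_id, grade, score_1, score_2, margin, pair_distance
    threshold: float
    delta: float

    @property
    def grade_counts(self) -> dict[str, int]:
        counts = self.table["grade"].value_counts().to_dict()
        return {g: int(counts.get(g, 0)) for g in GRADES}

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "delta": self.delta,
            "samples": self.table.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "StratificationResult":
        return cls(
            table=pd.DataFrame(payload["samples"]),
            threshold=payload["threshold"],
            delta=payload["delta"],
        )


def _grade(s1: float, s2: float, threshold: float, delta: float) -> str:
    if s1 >= threshold + delta and s2 >= threshold + delta:
        return "OSCC-grade"
    if s1 <= threshold - delta and s2 <= threshold - delta:
        return "HK-grade"
    return "borderline"


def stratify(
    model: PLSDAModel, oed_spectra: SpectrumSet, delta: float = 0.0
) -> StratificationResult:
    """Grade every OED sample from its two representative spectra.

    ``oed_spectra`` must carry exactly two rows per sample and be
    preprocessed identically to the model's training data.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    rows = []
    for sample_id, pair in oed_spectra.groupby("sample_id"):
        if pair.n_spectra != 2:
            raise ValueError(
                f"sample {sample_id} has {pair.n_spectra} spectra; exactly 2 required"
            )
        s1, s2 = model.predict_scores(pair)
        rows.append(
            {
                "sample_id": sample_id,
                "grade": _grade(s1, s2, model.threshold, delta),
                "score_1": float(s1),
                "score_2": float(s2),
                "margin": float(min(abs(s1 - model.threshold), abs(s2 - model.threshold))),
                "pair_distance": float(
                    np.linalg.norm(pair.intensities[0] - pair.intensities[1])
                ),
            }
        )
    return StratificationResult(
        table=pd.DataFrame(rows), threshold=model.threshold, delta=delta
    )


def stratification_report(result: StratificationResult) -> pd.DataFrame:
    """Per-sample report table (grade, scores, margin, pair distance).

    ``pair_distance`` is the Euclidean distance between the sample's two
    representative spectra - the length of the line connecting them in a
    score-plot rendering, a proxy for intra-sample heterogeneity.
    """
    if result.table.empty:
        raise ValueError("empty stratification result")
    return result.table.copy()
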