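"""Stent comparison: expansion-ratio summary and the five-indicator
rank scoring.

The pilot scoring ranks each of five indicators (radial stiffness,
degradation slowness, residual volume, mean stress level, final diameter)
across the compared stents; the best receives n points, the worst 1, ties
the mean of the tied ranks, and the total is the equally-weighted sum.
All five indicators are scored "greater is better" — degradation must
therefore be supplied as the day-180 mean normalized molecular weight
(higher = slower degradation = better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["INDICATORS", "ScoreCard", "score", "expansion_ratio"]

INDICATORS = (
    "radial_stiffness",
    "degradation",
    "residual_volume",
    "mean_stress",
    "final_diameter",
)


@dataclass
class ScoreCard:
    """Per-stent rank scores (n best ... 1 worst) and totals."""

    scores: pd.DataFrame  # index = stent names, columns = INDICATORS
    totals: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["total"] = self.totals
        return out

    def table(self) -> str:
        """Plain-text score matrix (a textual heat map)."""
        return self.to_frame().to_string(float_format=lambda v: f"{v:.1f}")


def score(
    indicators: pd.DataFrame | dict,
    weights: dict | None = None,
) -> ScoreCard:
    """Rank-score stents on the five indicators.

    ``indicators``: rows = stents, columns = the five indicator names,
    values oriented so that greater is better.  Ties receive the mean of
    the tied rank scores.  ``weights`` optionally weights the totals
    (default: equal weights of 1).
    """
    df = pd.DataFrame(indicators)
    missing = [c for c in INDICATORS if c not in df.columns]
    if missing:
        raise ValueError(f"missing indicator(s): {', '.join(missing)}")
    df = df[list(INDICATORS)]
    if df.isna().any().any():
        raise ValueError("indicator values must not be missing")
    ranks = df.apply(lambda col: rankdata(col.to_numpy()), axis=0)
    scores = pd.DataFrame(ranks, index=df.index, columns=df.columns)
    w = pd.Series({c: 1.0 for c in INDICATORS})
    if weights:
        for k, v in weights.items():
            if k not in INDICATORS:
                raise ValueError(f"unknown indicator {k!r}")
            w[k] = float(v)
    totals = (scores * w).sum(axis=1)
    return ScoreCard(scores=scores, totals=totals)


def expansion_ratio(D_post: float, D_lumen: float) -> tuple[float, bool]:
    """Post-recoil diameter over unloaded lumen diameter, 2 decimals.

    Returns (ratio, in_clinical_range); the clinical deployment window is
    a ratio between 1.0 and 1.1.
    """
    if D_lumen <= 0.0:
        raise ValueError("lumen diameter must be positive")
    r = round(D_post / D_lumen, 2)
    return r, 1.0 <= r <= 1.1
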