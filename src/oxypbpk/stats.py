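"""Meta-analysis pooling and model-performance statistics.

The pooling stage combines per-study summaries (n, mean, SD) of plasma
4β-OHC into a sample-size-weighted mean and a pooled CV.  By default the
pooled variance follows the law of total variance over study membership —
within-study variance plus the n-weighted dispersion of study means — which
equals the variance of the concatenated pseudo-sample; a within-only mode is
provided for comparison.

Model performance uses average fold error (AFE, bias) and absolute average
fold error (AAFE, precision) on log10 predicted/observed ratios, the flat
1.25-fold and 2-fold ratio criteria, and the Guest acceptance limits for DDI
ratios, which tighten toward unity as the observed ratio approaches 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "StudyRecord",
    "pooled_mean_cv",
    "afe",
    "aafe",
    "guest_limits",
    "AssessmentResult",
    "ratio_table",
]


class StudyRecord(BaseModel):
    """Summary statistics of one literature study."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    n: int = Field(ge=1)
    mean: float = Field(gt=0.0, description="ng/mL")
    sd: float = Field(ge=0.0, description="ng/mL")
    ethnicity: str = "unspecified"
    sex: str = "mixed"


def pooled_mean_cv(
    records: Sequence[StudyRecord], include_between: bool = True
) -> tuple[float, float]:
    """Sample-size-weighted mean and pooled CV (%) of study summaries.

    With ``include_between`` (default) the pooled SD combines within-study
    variance and the weighted dispersion of study means around the pooled
    mean; otherwise only the within-study component is pooled.
    """
    if not records:
        raise ValueError("records must be non-empty")
    n = np.array([r.n for r in records], dtype=float)
    means = np.array([r.mean for r in records])
    sds = np.array([r.sd for r in records])
    total = n.sum()
    wmean = float((n * means).sum() / total)
    var_within = (n * sds**2).sum() / total
    var = var_within + ((n * (means - wmean) ** 2).sum() / total if include_between else 0.0)
    cv = float(np.sqrt(var) / wmean * 100.0)
    return wmean, cv


def _check_pairs(predicted: Sequence[float], observed: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be 1-D sequences of equal length")
    if pred.size == 0:
        raise ValueError("predicted and observed must be non-empty")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("predicted and observed values must be positive")
    return pred, obs


def afe(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Average fold error: 10^(mean log10(pred/obs)).  >1 means overprediction."""
    pred, obs = _check_pairs(predicted, observed)
    return float(10.0 ** np.mean(np.log10(pred / obs)))


def aafe(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Absolute average fold error: 10^(mean |log10(pred/obs)|); always >= 1."""
    pred, obs = _check_pairs(predicted, observed)
    return float(10.0 ** np.mean(np.abs(np.log10(pred / obs))))


def guest_limits(observed_ratio: float, delta: float = 1.25) -> tuple[float, float]:
    """Guest acceptance bounds on predicted/observed for one DDI ratio.

    With R' = max(R, 1/R): L = (delta + 2(R'−1)) / R'; the acceptance band is
    (1/L, L).  At R = 1 this is the (1/delta, delta) band; as R → ∞ it
    relaxes to the classic two-fold limits.  Symmetric under R → 1/R.
    """
    if observed_ratio <= 0:
        raise ValueError("observed_ratio must be > 0")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    r = max(observed_ratio, 1.0 / observed_ratio)
    limit = (delta + 2.0 * (r - 1.0)) / r
    return 1.0 / limit, limit


@dataclass
class AssessmentResult:
    """Per-study prediction ratios with acceptance flags and summary errors."""

    table: pd.DataFrame
    afe: float
    aafe: float

    @property
    def all_within_twofold(self) -> bool:
        return bool(self.table["twofold_pass"].all())


def ratio_table(
    predicted: Sequence[float],
    observed: Sequence[float],
    labels: Sequence[str] | None = None,
    *,
    guest: bool = False,
    delta: float = 1.25,
) -> AssessmentResult:
    """Per-study predicted/observed ratios with 1.25-fold, 2-fold and Guest flags.

    With ``guest=True`` the observed values are treated as DDI ratios and each
    prediction is additionally checked against its Guest band.
    """
    pred, obs = _check_pairs(predicted, observed)
    if labels is None:
        labels = [f"study_{i + 1}" for i in range(pred.size)]
    if len(labels) != pred.size:
        raise ValueError("labels length must match predicted/observed")
    ratios = pred / obs
    rows = []
    for label, p, o, ratio in zip(labels, pred, obs, ratios):
        row = {
            "study": label,
            "predicted": p,
            "observed": o,
            "ratio": ratio,
            "within_1p25_pass": 1.0 / 1.25 <= ratio <= 1.25,
            "twofold_pass": 0.5 <= ratio <= 2.0,
        }
        if guest:
            lo, hi = guest_limits(o, delta)
            row["guest_lower"], row["guest_upper"] = lo, hi
            row["guest_pass"] = lo <= ratio <= hi
        rows.append(row)
    return AssessmentResult(table=pd.DataFrame(rows), afe=afe(pred, obs), aafe=aafe(pred, obs))
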