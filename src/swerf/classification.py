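"""CLP/GHS STOT RE classification and validation statistics.

The CLP regulation (EC 1272/2008, aligned with the UN GHS) sets generic
concentration limits for mixtures containing a fine fraction of
crystalline silica, assessed here on the SWeRF_CS in percent w/w:

    >= 10%        STOT RE category 1
    1% .. < 10%   STOT RE category 2 (the 1% lower bound is inclusive)
    < 1%          no hazard classification

Thresholds compare full-precision values; rounding happens only for
display, so a 0.96% never rounds up into a hazard class.

Also provided: repeatability statistics (mean, sample SD) and the squared
Pearson correlation used to quantify agreement between the calculated and
sedimentation routes.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "StotCategory",
    "ClassificationOutcome",
    "classify",
    "repeatability_stats",
    "method_agreement_r2",
    "render_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


class StotCategory(str, enum.Enum):
    STOT_RE_1 = "STOT_RE_1"
    STOT_RE_2 = "STOT_RE_2"
    NOT_CLASSIFIED = "NOT_CLASSIFIED"


@dataclass(frozen=True)
class ClassificationOutcome:
    category: StotCategory
    swerf_cs_percent: float
    rule_applied: str


def classify(swerf_cs_percent: float) -> ClassificationOutcome:
    """Apply the CLP generic concentration limits to a SWeRF_CS in percent."""
    if not (0.0 <= swerf_cs_percent <= 100.0):
        raise DomainError(
            f"swerf_cs_percent must lie in [0, 100], got {swerf_cs_percent!r}"
        )
    if swerf_cs_percent >= 10.0:
        return ClassificationOutcome(
            StotCategory.STOT_RE_1,
            swerf_cs_percent,
            "fine-fraction CS >= 10% w/w: STOT RE 1",
        )
    if swerf_cs_percent >= 1.0:
        return ClassificationOutcome(
            StotCategory.STOT_RE_2,
            swerf_cs_percent,
            "fine-fraction CS in [1%, 10%) w/w: STOT RE 2",
        )
    return ClassificationOutcome(
        StotCategory.NOT_CLASSIFIED,
        swerf_cs_percent,
        "fine-fraction CS < 1% w/w: no classification",
    )


def repeatability_stats(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n−1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DomainError("repeatability statistics need at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def method_agreement_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two method series.

    Used to quantify recovery/agreement between the calculated and
    sedimentation routes; symmetric in its arguments and invariant under
    affine transforms of either.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise DomainError("series must have equal length")
    if xa.size < 3:
        raise DomainError("agreement statistic needs at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DomainError("both series need nonzero variance")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return r * r


def render_report(results: pd.DataFrame, fmt: str = "md") -> str:
    """Render a SWeRF results table with classification, as markdown or JSON.

    ``results`` must carry ``sample`` and ``swerf_percent`` columns and
    may carry ``swerf_cs_percent``; a ``classification`` column is added
    from the CLP limits (classification requires SWeRF_CS — rows without
    it are marked not assessed).
    """
    required = {"sample", "swerf_percent"}
    missing = required - set(results.columns)
    if missing:
        raise DomainError(f"report input is missing columns {sorted(missing)}")
    frame = results.copy()
    if "swerf_cs_percent" not in frame.columns:
        frame["swerf_cs_percent"] = np.nan

    def _cls(v) -> str:
        if pd.isna(v):
            return "not assessed"
        return classify(float(v)).category.value

    frame["classification"] = frame["swerf_cs_percent"].map(_cls)

    if fmt == "json":
        payload = {
            "swerf_report_version": REPORT_SCHEMA_VERSION,
            "results": json.loads(
                frame.to_json(orient="records", double_precision=10)
            ),
        }
        return json.dumps(payload, indent=2)
    if fmt == "md":
        lines = [
            "| Sample | SWeRF (%) | SWeRF_CS (%) | Classification |",
            "|---|---|---|---|",
        ]
        for row in frame.itertuples(index=False):
            cs = (
                "–"
                if pd.isna(row.swerf_cs_percent)
                else f"{row.swerf_cs_percent:.1f}"
            )
            lines.append(
                f"| {row.sample} | {row.swerf_percent:.1f} | {cs} "
                f"| {row.classification} |"
            )
        return "\n".join(lines)
    raise DomainError(f"unknown report format {fmt!r}")
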