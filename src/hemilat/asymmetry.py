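"""The AS(X) hemispheric laterality index.

For any nonnegative network metric X evaluated on the right and left
hemispheric networks,

    AS(X) = 100 * [X(R) - X(L)] / [X(R) + X(L)],

bounded in [-100, +100].  Negative AS indicates a leftward advantage of
the metric.  The one interpretive exception is the characteristic path
length L_w, where longer paths mean *less* efficient integration:
positive AS(L_w) therefore indicates a leftward advantage of global
integration.  The stored number always follows the formula unmodified;
the flip is interpretation only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .metrics import GlobalMetrics

logger = logging.getLogger(__name__)

#: Global metrics for which an AS score is reported.
GLOBAL_AS_METRICS = ("c_w", "l_w", "sigma", "e_global", "e_local")


@dataclass(frozen=True)
class AsymmetryScore:
    metric: str
    x_left: float
    x_right: float
    as_value: float  # NaN where undefined
    subject_id: str = ""
    modality: str = ""


def asymmetry_score(x_right: float, x_left: float) -> float:
    """``100 * (X(R) - X(L)) / (X(R) + X(L))``; NaN if both are zero."""
    if x_right < 0 or x_left < 0:
        raise ValueError("asymmetry index requires nonnegative metric values")
    total = x_right + x_left
    if total == 0:
        logger.warning("asymmetry undefined: both hemisphere values are zero")
        return math.nan
    # mathematically bounded in [-100, 100]; clamp floating-point overshoot
    return min(100.0, max(-100.0, 100.0 * (x_right - x_left) / total))


def subject_asymmetry_profile(
    gm_left: GlobalMetrics,
    gm_right: GlobalMetrics,
    enodal_left: np.ndarray | None = None,
    enodal_right: np.ndarray | None = None,
    subject_id: str = "",
    modality: str = "",
    region_names: list[str] | None = None,
) -> list[AsymmetryScore]:
    """One AS per global metric and, if given, per homotopic region pair.

    Regional efficiency vectors must be homotopically aligned (index k
    in the left vector is the same region as index k in the right).
    """
    scores = []
    for name in GLOBAL_AS_METRICS:
        x_l = getattr(gm_left, "lam" if name == "lambda" else name)
        x_r = getattr(gm_right, "lam" if name == "lambda" else name)
        if x_l is None or x_r is None:
            continue
        scores.append(
            AsymmetryScore(
                metric=name,
                x_left=float(x_l),
                x_right=float(x_r),
                as_value=asymmetry_score(float(x_r), float(x_l)),
                subject_id=subject_id,
                modality=modality,
            )
        )
    if enodal_left is not None or enodal_right is not None:
        if enodal_left is None or enodal_right is None or len(enodal_left) != len(enodal_right):
            raise ValueError("regional efficiency vectors are misaligned")
        names = region_names or [f"pair{k + 1:02d}" for k in range(len(enodal_left))]
        if len(names) != len(enodal_left):
            raise ValueError("region name list does not match the regional vectors")
        for name, x_l, x_r in zip(names, enodal_left, enodal_right):
            scores.append(
                AsymmetryScore(
                    metric=f"e_nodal_{name}",
                    x_left=float(x_l),
                    x_right=float(x_r),
                    as_value=asymmetry_score(float(x_r), float(x_l)),
                    subject_id=subject_id,
                    modality=modality,
                )
            )
    return scores
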