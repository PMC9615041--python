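"""Two-proportion Z tests on peak annotation-class composition.

Compares each class's frequency among the dynamic peaks against the rest
of the peaks with the classic pooled two-proportion Z statistic

    Z = (p1 - p2) / sqrt(pbar * (1 - pbar) * (1/n1 + 1/n2)),

where pbar is the pooled proportion; the two-sided p-value comes from the
standard normal distribution. No continuity correction and, by default,
no multiple-testing adjustment across classes (each test is judged at
p <= 0.05); a BH option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ProportionTestResult:
    category: str
    p1: float
    p2: float
    n1: int
    n2: int
    pooled: float
    z: float
    p: float
    significant: bool


def two_proportion_z(k1: int, n1: int, k2: int, n2: int, category: str = "") -> ProportionTestResult:
    """Pooled two-proportion Z test; degenerate pooled proportions give Z=0, p=1."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("population sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        z, p = 0.0, 1.0
    else:
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        z = (p1 - p2) / se
        p = 2.0 * stats.norm.sf(abs(z))
    return ProportionTestResult(category, p1, p2, n1, n2, pooled, float(z), float(p), p <= 0.05)


def compare_composition(
    annotations: pd.DataFrame,
    dynamic_flags: pd.Series | np.ndarray,
    adjust: bool = False,
) -> pd.DataFrame:
    """Test every location and transcript class: dynamic peaks vs the rest.

    ``annotations`` must carry location_class and transcript_class columns
    (one row per peak, aligned with ``dynamic_flags``). Returns one row per
    (axis, class) with counts, Z, p and the significance flag. With zero
    dynamic or zero non-dynamic peaks an empty table is returned with a
    warning.
    """
    flags = np.asarray(dynamic_flags, dtype=bool)
    if len(flags) != len(annotations):
        raise ValueError("dynamic_flags must align with annotations")
    n1, n2 = int(flags.sum()), int((~flags).sum())
    if n1 == 0 or n2 == 0:
        logger.warning("degenerate split (%d dynamic, %d rest): no tests run", n1, n2)
        return pd.DataFrame(
            columns=["axis", "category", "k1", "n1", "k2", "n2", "Z", "p", "significant"]
        )
    rows = []
    for axis in ("location_class", "transcript_class"):
        for cls in sorted(annotations[axis].unique()):
            in_cls = (annotations[axis] == cls).to_numpy()
            k1 = int((in_cls & flags).sum())
            k2 = int((in_cls & ~flags).sum())
            res = two_proportion_z(k1, n1, k2, n2, category=cls)
            rows.append(
                {
                    "axis": axis,
                    "category": cls,
                    "k1": k1,
                    "n1": n1,
                    "k2": k2,
                    "n2": n2,
                    "Z": res.z,
                    "p": res.p,
                    "significant": res.significant,
                }
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["padj"] <= 0.05
    return out
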