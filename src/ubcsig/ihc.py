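"""Four-marker immunohistochemistry scoring and basal/luminal subtype calls.

Percent-positive tumor-cell estimates are quantized to a four-tier score.
Standard markers (CK5/6, CK14, CK20, pSTAT3, MYC, FOSL1): 0 below 5%,
1 in [5, 25), 2 in [25, 50), 3 at or above 50%.  UPK2, a highly specific
terminal-differentiation marker, uses a lower cut-off: 0 only when negative
(exactly 0%), 1 below 10%, 2 in [10, 25), 3 at or above 25%.

Subtype decision on the (CK5/6, CK14, CK20, UPK2) tiers:

* basal when (i) CK5/6 or CK14 is score 3, or (ii) both CK5/6 and CK14 are
  score 2 with all luminal markers at score 0-1;
* luminal when (i) CK20 is score 3, or UPK2 is score 2-3 with all basal
  markers at score 0-1, or (ii) CK20 and UPK2 are both score 1-2 with all
  basal markers at score 0-1;
* otherwise non-type.  If the basal and luminal criteria both hold (a
  score-3 basal marker together with CK20 score 3) the case is a flagged
  conflict and called non-type.

Score-3 ("high") marker claims are unconditional; the weaker luminal
clauses require absent/focal basal staining, so mixed moderate-expression
cases fall to non-type rather than being called on a single moderate
marker.

"High" expression of any marker means tier 2-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubtypeCall",
    "quantize_score",
    "call_subtype",
    "dichotomize",
    "contingency_test",
    "call_cohort",
    "SUBTYPE_MARKERS",
]

SUBTYPE_MARKERS = ("CK5/6", "CK14", "CK20", "UPK2")
_UPK2_BINS = ((0.0, 0), (10.0, 1), (25.0, 2), (100.0, 3))


@dataclass
class SubtypeCall:
    call: str           # basal / luminal / non-type
    rule_fired: str
    conflict: bool


def quantize_score(percent: float, marker: str = "CK5/6") -> int:
    """Four-tier score from a percent-positive value in [0, 100]."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    if marker == "UPK2":
        if percent == 0.0:
            return 0
        if percent < 10.0:
            return 1
        if percent < 25.0:
            return 2
        return 3
    if percent < 5.0:
        return 0
    if percent < 25.0:
        return 1
    if percent < 50.0:
        return 2
    return 3


def call_subtype(scores) -> SubtypeCall:
    """Basal/luminal/non-type decision from the four subtype-marker tiers.

    ``scores`` maps marker name to tier for CK5/6, CK14, CK20 and UPK2.
    """
    missing = [m for m in SUBTYPE_MARKERS if m not in scores]
    if missing:
        raise KeyError(f"missing marker scores: {missing}")
    s = {m: int(scores[m]) for m in SUBTYPE_MARKERS}
    for m, v in s.items():
        if v not in (0, 1, 2, 3):
            raise ValueError(f"tier score for {m} must be 0-3, got {v}")
    ck56, ck14, ck20, upk2 = s["CK5/6"], s["CK14"], s["CK20"], s["UPK2"]

    luminal_low = ck20 <= 1 and upk2 <= 1
    basal_low = ck56 <= 1 and ck14 <= 1
    basal_i = ck56 == 3 or ck14 == 3
    basal_ii = ck56 == 2 and ck14 == 2 and luminal_low
    # high CK20 is unconditionally luminal; the weaker UPK2 2-3 and
    # CK20/UPK2 1-2 clauses require absent/focal basal markers
    luminal_i = ck20 == 3 or (upk2 >= 2 and basal_low)
    luminal_ii = (1 <= ck20 <= 2) and (1 <= upk2 <= 2) and basal_low

    basal = basal_i or basal_ii
    luminal = luminal_i or luminal_ii
    if basal and luminal:
        return SubtypeCall("non-type", "conflict", True)
    if basal:
        return SubtypeCall("basal", "basal_i" if basal_i else "basal_ii", False)
    if luminal:
        return SubtypeCall(
            "luminal", "luminal_i" if luminal_i else "luminal_ii", False
        )
    return SubtypeCall("non-type", "none", False)


def dichotomize(score: int) -> str:
    """High (tier 2-3) vs low (tier 0-1) marker expression."""
    if score not in (0, 1, 2, 3):
        raise ValueError(f"tier score must be 0-3, got {score}")
    return "high" if score >= 2 else "low"


def contingency_test(
    table, method: str = "pearson"
) -> tuple[float, float]:
    """2x2 contingency test: Pearson chi-square (default), Yates, or Fisher."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.rint(t)):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    if method in ("pearson", "yates"):
        if np.any(stats.contingency.expected_freq(t) <= 0):
            raise ValueError("expected cell counts must be positive")
        chi2, p, _, _ = stats.chi2_contingency(t, correction=(method == "yates"))
        return float(chi2), float(p)
    if method == "fisher":
        odds, p = stats.fisher_exact(t)
        return float(odds), float(p)
    raise ValueError(f"unknown method {method!r}")


def call_cohort(panel: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Score and call every case in a panel table.

    ``panel`` must carry a ``case_id`` column plus the four subtype markers,
    as percent-positive values (``percent=True``) or pre-quantized tiers.
    Returns the input plus per-marker tiers, call, rule_fired and conflict.
    """
    out = panel.copy()
    for m in SUBTYPE_MARKERS:
        if m not in panel.columns:
            raise KeyError(f"panel is missing marker column {m!r}")
        if percent:
            out[f"{m}_tier"] = [quantize_score(v, m) for v in panel[m]]
        else:
            out[f"{m}_tier"] = panel[m].astype(int)
    calls = [
        call_subtype({m: row[f"{m}_tier"] for m in SUBTYPE_MARKERS})
        for _, row in out.iterrows()
    ]
    out["call"] = [c.call for c in calls]
    out["rule_fired"] = [c.rule_fired for c in calls]
    out["conflict"] = [c.conflict for c in calls]
    return out
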