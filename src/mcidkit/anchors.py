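"""Global Rating of Change (GRC) anchors.

Two anchor schemes:

* ``grc15`` — 15-point numeric transition rating from -7 (*very much
  worse*) to +7 (*very much better*), 0 = no change.  Analysed as seven
  categories: 0/±1 no change, ±2/±3 minimal, ±4/±5 moderate, ±6/±7
  large change (sign = improvement vs deterioration side).
* ``grc5`` — five-point verbal rating: much worse / somewhat worse /
  same / somewhat better / much better.

An anchor is *eligible* to define an MCID when its correlation with the
instrument change score reaches |r| >= 0.30, and *preferred* at
|r| >= 0.50.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GRC5_LEVELS",
    "GRC5_CODES",
    "GRC15_COLLAPSE",
    "AnchorRating",
    "AnchorEligibility",
    "CrossTabResult",
    "categorize",
    "collapse_grc15",
    "anchor_correlation",
    "cross_tabulate",
]

logger = logging.getLogger(__name__)

ELIGIBLE_R = 0.30
PREFERRED_R = 0.50

GRC5_LEVELS: tuple[str, ...] = (
    "much worse", "somewhat worse", "same", "somewhat better", "much better",
)
GRC5_CODES: Mapping[str, int] = {lvl: i - 2 for i, lvl in enumerate(GRC5_LEVELS)}

_GRC15_MAGNITUDE = {0: "no change", 1: "minimal", 2: "moderate", 3: "large"}

# Collapse of the seven 15-point categories onto the five verbal levels,
# used for cross-scheme agreement.  The ordinal structure is preserved:
# no change <-> same, minimal/moderate <-> somewhat, large <-> much,
# applied symmetrically.  This mapping is a documented assumption and can
# be overridden per call.
GRC15_COLLAPSE: Mapping[str, str] = {
    "no change": "same",
    "minimal improvement": "somewhat better",
    "moderate improvement": "somewhat better",
    "large improvement": "much better",
    "minimal deterioration": "somewhat worse",
    "moderate deterioration": "somewhat worse",
    "large deterioration": "much worse",
}


@dataclass(frozen=True)
class AnchorRating:
    """One patient's GRC rating at one follow-up."""

    patient_id: str
    timepoint: str
    scheme: str  # "grc15" | "grc5"
    value: int | str

    def __post_init__(self) -> None:
        _validate_rating(self.value, self.scheme)

    @property
    def category(self) -> str:
        return categorize(self.value, self.scheme)


@dataclass
class AnchorEligibility:
    """Anchor-change correlation and the 0.30 / 0.50 eligibility flags."""

    instrument: str
    scheme: str
    timepoint: str
    coefficient: float
    method: str  # "pearson" | "spearman"
    n: int

    @property
    def eligible(self) -> bool:
        return abs(self.coefficient) >= ELIGIBLE_R

    @property
    def preferred(self) -> bool:
        return abs(self.coefficient) >= PREFERRED_R


def _validate_rating(value, scheme: str) -> None:
    if scheme == "grc15":
        if not float(value).is_integer() or not -7 <= int(value) <= 7:
            raise ValueError(
                f"grc15 rating must be an integer in [-7, 7], got {value!r}"
            )
    elif scheme == "grc5":
        if value not in GRC5_LEVELS:
            raise ValueError(
                f"grc5 rating must be one of {GRC5_LEVELS}, got {value!r}"
            )
    else:
        raise ValueError(f"unknown anchor scheme {scheme!r}")


def categorize(value: int | str, scheme: str = "grc15") -> str:
    """Map a legal GRC rating to its change category.

    15-point ratings map by magnitude (0/±1 no change; ±2/±3 minimal;
    ±4/±5 moderate; ±6/±7 large) with the sign selecting the
    improvement vs deterioration side.  Five-point ratings map to
    themselves (identity).
    """
    _validate_rating(value, scheme)
    if scheme == "grc5":
        return str(value)
    v = int(value)
    mag = _GRC15_MAGNITUDE[abs(v) // 2]
    if mag == "no change":
        return "no change"
    side = "improvement" if v > 0 else "deterioration"
    return f"{mag} {side}"


def collapse_grc15(
    value: int, mapping: Mapping[str, str] = GRC15_COLLAPSE
) -> str:
    """Collapse a 15-point rating onto the five-point verbal levels."""
    return mapping[categorize(value, "grc15")]


def _normal_enough(x: np.ndarray) -> bool:
    """Skewness/kurtosis screen shared with the pipeline module."""
    from .pipeline import screen  # local import avoids a cycle

    if len(x) < 8 or np.std(x) == 0:
        return False
    return screen(x).normal


def anchor_correlation(
    changes: Sequence[float],
    ratings: Sequence,
    method: str = "auto",
    scheme: str = "grc15",
    instrument: str = "",
    timepoint: str = "",
) -> AnchorEligibility:
    """Correlate instrument change scores with matched GRC ratings.

    ``method="auto"`` selects Pearson when both variables pass the
    skewness/kurtosis normality screen, Spearman otherwise; five-point
    ratings are always treated as non-parametric (Spearman).
    """
    x = np.asarray(changes, dtype=float)
    if scheme == "grc5":
        r_vals = np.array(
            [np.nan if pd.isna(v) else GRC5_CODES[v] for v in ratings],
            dtype=float,
        )
    else:
        r_vals = np.asarray(ratings, dtype=float)
    if len(x) != len(r_vals):
        raise ValueError("changes and ratings must be matched 1:1")
    mask = ~(np.isnan(x) | np.isnan(r_vals))
    x, r_vals = x[mask], r_vals[mask]
    if len(x) < 3:
        raise ValueError(f"need >= 3 matched complete pairs, got {len(x)}")
    if np.std(x) == 0 or np.std(r_vals) == 0:
        raise ValueError(
            "zero variance in changes or ratings; correlation undefined"
        )
    if method == "auto":
        if scheme == "grc5":
            method = "spearman"
        else:
            method = ("pearson"
                      if _normal_enough(x) and _normal_enough(r_vals)
                      else "spearman")
    if method == "pearson":
        coef = float(stats.pearsonr(x, r_vals).statistic)
    elif method == "spearman":
        coef = float(stats.spearmanr(x, r_vals).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return AnchorEligibility(
        instrument=instrument, scheme=scheme, timepoint=timepoint,
        coefficient=coef, method=method, n=len(x),
    )


@dataclass
class CrossTabResult:
    """Agreement between the collapsed 15-point and five-point schemes."""

    table: pd.DataFrame  # rows: collapsed grc15 level; cols: grc5 level
    percent_concordant: float
    spearman: float
    n: int
    n_dropped: int


def cross_tabulate(
    grc15_values: Sequence,
    grc5_labels: Sequence,
    mapping: Mapping[str, str] = GRC15_COLLAPSE,
) -> CrossTabResult:
    """Cross-tabulate the two anchor schemes on matched patients.

    The 15-point ratings are first collapsed onto the five verbal
    levels; concordance is the percentage of patients on the diagonal.
    The rank correlation is computed between the raw -7..+7 values and
    the ordinal codes of the five-point ratings.  Unmatched (missing)
    patients are dropped with a logged count.
    """
    g15 = pd.Series(list(grc15_values), dtype="float64")
    g5 = pd.Series(list(grc5_labels), dtype="object")
    if len(g15) != len(g5):
        raise ValueError("ratings must be matched 1:1 on patients")
    mask = g15.notna() & g5.notna()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("cross_tabulate: dropped %d unmatched patients", n_dropped)
    g15, g5 = g15[mask], g5[mask]
    if len(g15) == 0:
        raise ValueError("no matched pairs to tabulate")
    collapsed = g15.astype(int).map(lambda v: collapse_grc15(v, mapping))
    table = pd.crosstab(collapsed, g5).reindex(
        index=list(GRC5_LEVELS), columns=list(GRC5_LEVELS), fill_value=0
    )
    concordant = int(np.trace(table.to_numpy()))
    codes5 = g5.map(GRC5_CODES).astype(float)
    rho = float(stats.spearmanr(g15, codes5).statistic) \
        if g15.nunique() > 1 and codes5.nunique() > 1 else float("nan")
    return CrossTabResult(
        table=table,
        percent_concordant=100.0 * concordant / len(g15),
        spearman=rho,
        n=int(len(g15)),
        n_dropped=n_dropped,
    )
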