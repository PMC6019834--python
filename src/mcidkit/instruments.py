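"""Scoring of COPD health-status questionnaires.

Three instrument shapes are supported:

* **CAT-like** — fixed item count, integer items, total = sum of items
  (CAT: 8 items scored 0-5, total 0-40; higher = worse).
* **CCQ-like** — total = mean of item scores (CCQ: 10 items scored 0-6,
  total 0-6), with named domains scored the same way on item subsets.
* **SGRQ-like** — weighted scoring: each item carries a nonnegative
  weight and the total is the weight-normalised fraction of maximal
  impairment mapped onto the instrument scale (SGRQ: 0-100).  The real
  SGRQ item weights are licensed and are therefore supplied via config;
  a synthetic weight set ships for testing.

All totals can be standardised to a common 0-100 scale
(``value * 100 / scale_max``) so that change scores of different
instruments are directly comparable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InstrumentSpec",
    "ItemResponseSet",
    "ScoreRecord",
    "ScoringError",
    "CAT",
    "CCQ",
    "synthetic_sgrq",
    "score_instrument",
    "standardize",
    "instrument_from_config",
    "score_long_table",
]

SCORING_RULES = ("sum", "mean_of_items", "weighted")


class ScoringError(ValueError):
    """Raised for invalid instrument definitions or item responses."""


@dataclass(frozen=True)
class InstrumentSpec:
    """Declarative definition of a questionnaire.

    Parameters
    ----------
    name : str
        Instrument identifier (e.g. ``"CAT"``).
    n_items : int
        Number of items.
    item_min, item_max : float
        Legal per-item score range.
    scoring_rule : {"sum", "mean_of_items", "weighted"}
        How item responses combine into the total score.
    scale_max : float
        Maximum achievable total under the scoring rule (CAT 40,
        CCQ 6, SGRQ 100).  Used for standardisation to 0-100.
    domains : mapping of str to tuple of int, optional
        Named item subsets (0-based indices) scored with the same rule.
    weights : tuple of float, optional
        Per-item nonnegative weights; required for the weighted rule.
    """

    name: str
    n_items: int
    item_min: float
    item_max: float
    scoring_rule: str
    scale_max: float
    domains: Mapping[str, tuple[int, ...]] | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise ScoringError(f"{self.name}: n_items must be positive")
        if not self.item_min < self.item_max:
            raise ScoringError(f"{self.name}: item_min must be < item_max")
        if self.scoring_rule not in SCORING_RULES:
            raise ScoringError(
                f"{self.name}: unknown scoring rule {self.scoring_rule!r}"
            )
        if self.scoring_rule == "weighted":
            if self.weights is None or len(self.weights) != self.n_items:
                raise ScoringError(
                    f"{self.name}: weighted rule requires one weight per item"
                )
            if any(w < 0 for w in self.weights):
                raise ScoringError(f"{self.name}: weights must be nonnegative")
        if self.domains:
            for dom, items in self.domains.items():
                if len(items) == 0:
                    raise ScoringError(f"{self.name}: domain {dom!r} is empty")
                if any(i < 0 or i >= self.n_items for i in items):
                    raise ScoringError(
                        f"{self.name}: domain {dom!r} references unknown items"
                    )
        # scale_max must equal the maximum achievable total under the rule
        achievable = self._max_achievable()
        if not np.isclose(self.scale_max, achievable):
            raise ScoringError(
                f"{self.name}: scale_max {self.scale_max} does not equal the "
                f"maximum achievable total {achievable}"
            )

    def _max_achievable(self) -> float:
        if self.scoring_rule == "sum":
            return self.n_items * self.item_max
        if self.scoring_rule == "mean_of_items":
            return float(self.item_max)
        return float(self.scale_max)  # weighted: normalised onto scale_max

    def validate_response(self, item: int, value: float) -> None:
        if not (self.item_min <= value <= self.item_max):
            raise ScoringError(
                f"{self.name}: item {item} value {value} outside "
                f"[{self.item_min}, {self.item_max}]"
            )


@dataclass
class ItemResponseSet:
    """Per-item responses of one patient at one timepoint.

    ``responses`` maps 0-based item index to value; missing items are
    absent from the mapping (or NaN).
    """

    patient_id: str
    timepoint: str
    instrument: str
    responses: Mapping[int, float] = field(default_factory=dict)


@dataclass
class ScoreRecord:
    """Scored questionnaire: total, domain scores, 0-100 standardised."""

    patient_id: str
    timepoint: str
    instrument: str
    total: float
    domain_scores: dict[str, float]
    standardized: float
    complete: bool


# ---------------------------------------------------------------------------
# Built-in instrument definitions

CAT = InstrumentSpec(
    name="CAT", n_items=8, item_min=0, item_max=5,
    scoring_rule="sum", scale_max=40,
)

CCQ = InstrumentSpec(
    name="CCQ", n_items=10, item_min=0, item_max=6,
    scoring_rule="mean_of_items", scale_max=6,
    domains={
        "symptoms": (0, 1, 4, 5),
        "functional_status": (6, 7, 8, 9),
        "mental_status": (2, 3),
    },
)


def synthetic_sgrq(n_items: int = 50, seed: int = 12345) -> InstrumentSpec:
    """SGRQ-shaped weighted instrument with a *synthetic* weight set.

    The licensed SGRQ item weights are not redistributable; this factory
    produces a deterministic stand-in with the same computational shape
    (50 binary items, positive weights, 0-100 total) for testing and
    examples.  Real analyses must load the licensed weights via
    :func:`instrument_from_config`.
    """
    rng = np.random.default_rng(seed)
    weights = tuple(np.round(rng.uniform(10.0, 100.0, size=n_items), 1))
    return InstrumentSpec(
        name="SGRQ", n_items=n_items, item_min=0, item_max=1,
        scoring_rule="weighted", scale_max=100, weights=weights,
    )


# ---------------------------------------------------------------------------
# Operations

def _apply_rule(
    spec: InstrumentSpec,
    items: Sequence[int],
    responses: Mapping[int, float],
    allow_missing: int,
) -> tuple[float, bool]:
    """Score one item subset.  Returns (value, complete)."""
    present = [i for i in items if i in responses
               and responses[i] is not None and not np.isnan(responses[i])]
    missing = len(items) - len(present)
    if spec.scoring_rule == "mean_of_items":
        if missing > allow_missing or not present:
            return float("nan"), False
        return float(np.mean([responses[i] for i in present])), True
    # sum and weighted rules require complete data: the source tables report
    # whole questionnaires as incomplete, never partially scored ones
    if missing > 0:
        return float("nan"), False
    vals = np.array([responses[i] for i in items], dtype=float)
    if spec.scoring_rule == "sum":
        return float(vals.sum()), True
    w = np.array([spec.weights[i] for i in items], dtype=float)
    unit = (vals - spec.item_min) / (spec.item_max - spec.item_min)
    return float(spec.scale_max * (w @ unit) / w.sum()), True


def score_instrument(
    spec: InstrumentSpec,
    items: ItemResponseSet | Mapping[int, float],
    allow_missing: int = 0,
) -> ScoreRecord:
    """Score a set of item responses under an instrument definition.

    ``allow_missing`` relaxes the strict no-missing policy for the
    ``mean_of_items`` rule only (mean over present items when at most
    that many items are missing).  Sum and weighted rules always require
    complete data; the record comes back flagged incomplete otherwise —
    missing items are never imputed.
    """
    if isinstance(items, ItemResponseSet):
        if items.instrument != spec.name:
            raise ScoringError(
                f"responses are for {items.instrument!r}, spec is {spec.name!r}"
            )
        responses = dict(items.responses)
        pid, tp = items.patient_id, items.timepoint
    else:
        responses = dict(items)
        pid, tp = "", ""
    for i, v in responses.items():
        if i < 0 or i >= spec.n_items:
            raise ScoringError(f"{spec.name}: unknown item index {i}")
        if v is not None and not np.isnan(v):
            spec.validate_response(i, v)

    all_items = tuple(range(spec.n_items))
    total, complete = _apply_rule(spec, all_items, responses, allow_missing)
    domain_scores: dict[str, float] = {}
    for dom, dom_items in (spec.domains or {}).items():
        domain_scores[dom], _ = _apply_rule(spec, dom_items, responses,
                                            allow_missing)
    return ScoreRecord(
        patient_id=pid, timepoint=tp, instrument=spec.name,
        total=total, domain_scores=domain_scores,
        standardized=standardize(spec, total) if complete else float("nan"),
        complete=complete,
    )


def standardize(spec: InstrumentSpec, value):
    """Rescale a total or change score to the common 0-100 scale.

    Linear: ``value * 100 / scale_max``; signs of change scores are
    preserved (negative = improvement).
    """
    if spec.scale_max <= 0:
        raise ScoringError(f"{spec.name}: invalid scale_max")
    return np.asarray(value, dtype=float) * 100.0 / spec.scale_max \
        if np.ndim(value) else float(value) * 100.0 / spec.scale_max


def instrument_from_config(source: str | Path | Mapping) -> InstrumentSpec:
    """Build an :class:`InstrumentSpec` from a JSON/YAML file or mapping."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = json.loads(text) if str(source).endswith(".json") \
            else yaml.safe_load(text)
    else:
        data = dict(source)
    if "domains" in data and data["domains"] is not None:
        data["domains"] = {k: tuple(v) for k, v in data["domains"].items()}
    if "weights" in data and data["weights"] is not None:
        data["weights"] = tuple(data["weights"])
    return InstrumentSpec(**data)


def score_long_table(
    df: pd.DataFrame,
    specs: Mapping[str, InstrumentSpec],
    allow_missing: int = 0,
) -> pd.DataFrame:
    """Score a long-format item table.

    Expects columns ``patient_id, timepoint, instrument, item, value``
    (0-based item index).  Returns one row per patient x timepoint x
    instrument with total, standardized and complete columns.
    """
    required = {"patient_id", "timepoint", "instrument", "item", "value"}
    if not required.issubset(df.columns):
        raise ScoringError(f"long table must have columns {sorted(required)}")
    out = []
    for (pid, tp, inst), grp in df.groupby(
            ["patient_id", "timepoint", "instrument"], sort=False):
        if inst not in specs:
            raise ScoringError(f"no spec for instrument {inst!r}")
        responses = dict(zip(grp["item"].astype(int), grp["value"]))
        rec = score_instrument(
            specs[inst],
            ItemResponseSet(str(pid), str(tp), inst, responses),
            allow_missing=allow_missing,
        )
        out.append({
            "patient_id": rec.patient_id, "timepoint": rec.timepoint,
            "instrument": rec.instrument, "total": rec.total,
            "standardized": rec.standardized, "complete": rec.complete,
            **{f"domain_{k}": v for k, v in rec.domain_scores.items()},
        })
    return pd.DataFrame(out)
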