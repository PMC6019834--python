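"""Synthetic longitudinal PRO cohorts with anchor ratings.

The generator emulates the statistical structure the MCID pipeline
assumes for an inpatient pulmonary-rehabilitation cohort:

* baseline totals per instrument drawn from correlated normals at the
  published cohort moments (CAT 20.2 ± 7.3, CCQ 2.9 ± 1.2,
  SGRQ 50.7 ± 17.3), kept within instrument range;
* follow-up totals correlated with baseline at a target intraclass
  correlation per instrument x period, plus a period treatment effect
  (largest at discharge, drifting back toward baseline);
* a 15-point GRC anchor built from a noisy monotone transform of the
  patient's composite standardised change, with the noise scale
  calibrated by bisection so the anchor-change correlation hits a
  per-period target;
* a five-point GRC at twelve months collapsed from the 15-point rating
  with ordinal label noise;
* a dropout schedule with intermittent missingness (some nine-month
  non-responders return at twelve months).

Identical config + seed always reproduces the identical cohort.  The
anchor noise calibration runs on a fixed-seed reference sample whose
seed does *not* depend on the cohort seed, so replicate cohorts that
differ only in seed share one data-generating law — this is what makes
parameter-recovery experiments well defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .anchors import GRC5_CODES, GRC5_LEVELS, GRC15_COLLAPSE, categorize
from .instruments import InstrumentSpec
from .pipeline import FOLLOWUPS, LongitudinalCohort, default_instruments
from .util import config_hash

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate",
    "subgroup_truth",
    "make_fixture",
    "FIXTURES",
]

_CALIBRATION_SEED = 2_000_003  # fixed: independent of the cohort seed
_TRUTH_SEED = 20_000_017


def _default_baseline_mean() -> dict[str, float]:
    return {"CAT": 20.2, "CCQ": 2.9, "SGRQ": 50.7}


def _default_baseline_sd() -> dict[str, float]:
    return {"CAT": 7.3, "CCQ": 1.2, "SGRQ": 17.3}


def _default_effects() -> dict[str, dict[str, float]]:
    # Full-cohort mean changes vs baseline: a discharge improvement that
    # drifts back toward baseline over the follow-up year.
    return {
        "CAT": {"T1": -3.1, "T2": -1.4, "T3": -0.9, "T4": -1.1, "T5": -0.9},
        "CCQ": {"T1": -0.6, "T2": -0.3, "T3": -0.1, "T4": -0.2, "T5": -0.2},
        "SGRQ": {"T1": -9.0, "T2": -5.4, "T3": -4.9, "T4": -5.2, "T5": -3.9},
    }


def _default_icc() -> dict[str, dict[str, float]]:
    return {
        "CAT": {"T1": 0.7, "T2": 0.6, "T3": 0.5, "T4": 0.6, "T5": 0.5},
        "CCQ": {"T1": 0.7, "T2": 0.6, "T3": 0.5, "T4": 0.7, "T5": 0.5},
        "SGRQ": {"T1": 0.7, "T2": 0.7, "T3": 0.7, "T4": 0.7, "T5": 0.6},
    }


def _default_anchor_validity() -> dict[str, float]:
    # |corr| between the 15-point GRC and the composite standardised
    # change, rising with recall period: weakest directly after the
    # programme, strongest around nine months.
    return {"T1": 0.30, "T2": 0.43, "T3": 0.47, "T4": 0.52, "T5": 0.49}


def _default_dropout() -> dict[str, int]:
    return {"T1": 451, "T2": 355, "T3": 319, "T4": 304, "T5": 309}


def _default_discharge_incomplete() -> dict[str, int]:
    return {"CAT": 2, "CCQ": 1, "SGRQ": 4}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Baseline moments, per-period effects, ICC targets, anchor-validity
    targets and the dropout schedule default to the published cohort
    conditions.  ``icc`` values are the target baseline-follow-up
    consistency correlations; ``icc = 1`` means the follow-up equals
    baseline plus the period effect exactly.  Dropout counts refer to a
    cohort of the default size and are scaled proportionally for other
    ``n_patients``.
    """

    n_patients: int = 451
    baseline_mean: dict[str, float] = field(
        default_factory=_default_baseline_mean)
    baseline_sd: dict[str, float] = field(default_factory=_default_baseline_sd)
    effects: dict[str, dict[str, float]] = field(
        default_factory=_default_effects)
    icc: dict[str, dict[str, float]] = field(default_factory=_default_icc)
    anchor_validity: dict[str, float] = field(
        default_factory=_default_anchor_validity)
    grc5_label_noise: float = 0.2
    dropout: dict[str, int] = field(default_factory=_default_dropout)
    discharge_incomplete: dict[str, int] = field(
        default_factory=_default_discharge_incomplete)
    n_missing_grc15_t1: int = 1
    cross_instrument_corr: float = 0.5  # shared baseline severity factor
    shared_response_frac: float = 0.5  # shared follow-up response factor
    anchor_gain: float = 2.4  # latent units per GRC step before rounding
    n_calibration: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for inst, sd in self.baseline_sd.items():
            if sd <= 0:
                raise ValueError(f"baseline_sd[{inst}] must be > 0")
        for inst, per_tp in self.icc.items():
            for tp, rho in per_tp.items():
                if not 0.0 <= rho <= 1.0:
                    raise ValueError(
                        f"icc[{inst}][{tp}] = {rho} outside [0, 1]")
        for tp, r in self.anchor_validity.items():
            if not 0.0 < r < 1.0:
                raise ValueError(
                    f"anchor_validity[{tp}] = {r} outside (0, 1)")
        if not 0.0 <= self.grc5_label_noise < 1.0:
            raise ValueError("grc5_label_noise must lie in [0, 1)")
        if not 0.0 <= self.cross_instrument_corr <= 1.0:
            raise ValueError("cross_instrument_corr must lie in [0, 1]")
        if not 0.0 <= self.shared_response_frac <= 1.0:
            raise ValueError("shared_response_frac must lie in [0, 1]")
        if min(self.dropout.values()) < 0:
            raise ValueError("dropout counts must be nonnegative")

    def calibration_key(self) -> str:
        """Hash of the fields the anchor calibration depends on."""
        return config_hash({
            "baseline_mean": self.baseline_mean,
            "baseline_sd": self.baseline_sd,
            "effects": self.effects,
            "icc": self.icc,
            "anchor_validity": self.anchor_validity,
            "cross_instrument_corr": self.cross_instrument_corr,
            "shared_response_frac": self.shared_response_frac,
            "anchor_gain": self.anchor_gain,
            "n_calibration": self.n_calibration,
        })


@dataclass
class SyntheticTruth:
    """Ground truth stored next to a generated cohort.

    ``latent`` holds the pre-dropout change scores, anchor ratings and
    the composite standardised change per patient, so recovery tests
    can compare pipeline estimates with what the generator actually
    produced.  ``noise_scales`` are the calibrated anchor noise scales
    per period; ``comp_scales`` the composite-change scale factors used
    to build the anchor latent.
    """

    config: GeneratorConfig
    latent: pd.DataFrame
    noise_scales: dict[str, float | None]
    comp_scales: dict[str, float]


# ---------------------------------------------------------------------------
# Core draws

def _draw_core(
    cfg: GeneratorConfig,
    n: int,
    rng: np.random.Generator,
    instruments: Mapping[str, InstrumentSpec],
):
    """Correlated baselines, follow-ups, deltas and composite change."""
    insts = list(cfg.baseline_mean)
    lam = cfg.cross_instrument_corr
    kap = cfg.shared_response_frac
    h = rng.standard_normal(n)  # shared severity factor
    B: dict[str, np.ndarray] = {}
    for inst in insts:
        v = rng.standard_normal(n)
        z = np.sqrt(lam) * h + np.sqrt(1.0 - lam) * v
        mu, sd = cfg.baseline_mean[inst], cfg.baseline_sd[inst]
        hi = instruments[inst].scale_max
        B[inst] = np.clip(mu + sd * z, 0.0, hi)
    F: dict[str, dict[str, np.ndarray]] = {inst: {} for inst in insts}
    delta: dict[str, dict[str, np.ndarray]] = {inst: {} for inst in insts}
    comp: dict[str, np.ndarray] = {}
    for tp in FOLLOWUPS:
        w = rng.standard_normal(n)  # shared response shock this period
        comp_parts = []
        for inst in insts:
            e = rng.standard_normal(n)
            eta = np.sqrt(kap) * w + np.sqrt(1.0 - kap) * e
            rho = cfg.icc[inst][tp]
            mu, sd = cfg.baseline_mean[inst], cfg.baseline_sd[inst]
            eff = cfg.effects[inst][tp]
            hi = instruments[inst].scale_max
            f = mu + eff + rho * (B[inst] - mu) \
                + sd * np.sqrt(1.0 - rho ** 2) * eta
            f = np.clip(f, 0.0, hi)
            F[inst][tp] = f
            d = f - B[inst]
            delta[inst][tp] = d
            comp_parts.append(d * 100.0 / hi)
        comp[tp] = np.mean(comp_parts, axis=0)
    return B, F, delta, comp


def _discretize_anchor(
    comp: np.ndarray,
    comp_sd: float,
    s: float,
    eps: np.ndarray,
    gain: float,
) -> np.ndarray:
    """15-point rating from composite change plus calibrated noise."""
    y = -comp / comp_sd  # positive latent = improvement
    latent = (y + s * eps) / np.sqrt(1.0 + s ** 2)
    return np.clip(np.rint(gain * latent), -7, 7).astype(int)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)))


_calibration_cache: dict[str, dict[str, tuple[float | None, float]]] = {}


def _calibrate(
    cfg: GeneratorConfig, instruments: Mapping[str, InstrumentSpec]
) -> dict[str, tuple[float | None, float]]:
    """Bisect the anchor noise scale per period to hit the target |r|.

    Runs on a fixed-seed reference sample of ``n_calibration`` patients;
    the result is cached per structural configuration.  Raises when a
    target correlation exceeds what the discretised 15-point scale can
    carry.
    """
    key = cfg.calibration_key()
    if key in _calibration_cache:
        return _calibration_cache[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    _, _, _, comp = _draw_core(cfg, cfg.n_calibration, rng, instruments)
    out: dict[str, tuple[float | None, float]] = {}
    for tp in FOLLOWUPS:
        c = comp[tp]
        sd = float(c.std())
        if sd < 1e-12:
            out[tp] = (None, 0.0)
            continue
        eps = rng.standard_normal(cfg.n_calibration)
        target = cfg.anchor_validity[tp]

        def realized(s: float) -> float:
            g = _discretize_anchor(c, sd, s, eps, cfg.anchor_gain)
            return _abs_corr(g.astype(float), c)

        lo, hi = 1e-3, 60.0
        r_max = realized(lo)
        if target > r_max - 0.005:
            raise ValueError(
                f"anchor_validity[{tp}] = {target} infeasible: the "
                f"discretised 15-point scale carries at most "
                f"|r| ~ {r_max:.3f} under this configuration"
            )
        if realized(hi) > target:
            raise ValueError(
                f"anchor_validity[{tp}] = {target} not reachable within "
                "the searched noise range"
            )
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if realized(mid) > target:
                lo = mid
            else:
                hi = mid
        out[tp] = (0.5 * (lo + hi), sd)
    _calibration_cache[key] = out
    return out


# ---------------------------------------------------------------------------
# Public API

def generate(
    cfg: GeneratorConfig,
    instruments: Mapping[str, InstrumentSpec] | None = None,
) -> tuple[LongitudinalCohort, SyntheticTruth]:
    """Generate one cohort plus its ground truth.

    Deterministic in ``cfg`` (including ``cfg.seed``).
    """
    cfg.validate()
    if instruments is None:
        instruments = default_instruments()
    instruments = {k: instruments[k] for k in cfg.baseline_mean}
    calib = _calibrate(cfg, instruments)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    insts = list(cfg.baseline_mean)

    B, F, delta, comp = _draw_core(cfg, n, rng, instruments)

    grc15: dict[str, np.ndarray] = {}
    for tp in FOLLOWUPS:
        eps = rng.standard_normal(n)
        s, comp_sd = calib[tp]
        if s is None or comp_sd == 0.0:
            grc15[tp] = np.zeros(n, dtype=int)
        else:
            grc15[tp] = _discretize_anchor(
                comp[tp], comp_sd, s, eps, cfg.anchor_gain)

    # five-point GRC at T5: collapse the 15-point categories, then apply
    # ordinal label noise (shift one level, clipped to the scale ends)
    codes = np.array([
        GRC5_CODES[GRC15_COLLAPSE[categorize(int(v), "grc15")]]
        for v in grc15["T5"]
    ])
    noisy = rng.random(n) < cfg.grc5_label_noise
    shift = rng.choice([-1, 1], size=n)
    codes = np.where(noisy, np.clip(codes + shift, -2, 2), codes)
    grc5 = np.array([GRC5_LEVELS[c + 2] for c in codes], dtype=object)

    # covariates at the published cohort moments
    age = np.round(rng.normal(57.9, 6.6, n), 1)
    sex = np.where(rng.random(n) < 0.65, "male", "female")
    fev1 = np.round(np.clip(rng.normal(50.4, 15.1, n), 15.0, 95.0), 1)
    gold = rng.choice(["II", "III", "IV"], size=n, p=[0.503, 0.390, 0.107])
    pack_years = np.round(np.clip(rng.normal(42.6, 23.5, n), 0.0, None), 1)

    # dropout schedule with T5 re-entry: observed set at each follow-up
    # is a prefix of one permutation, so T4 completers are a subset of
    # T5 completers and the returnees were observed at T3
    base_count = max(cfg.dropout.values())
    counts = {
        tp: min(n, int(round(cfg.dropout[tp] * n / base_count)))
        for tp in FOLLOWUPS
    }
    order = rng.permutation(n)
    observed = {tp: np.zeros(n, dtype=bool) for tp in FOLLOWUPS}
    for tp in FOLLOWUPS:
        observed[tp][order[: counts[tp]]] = True

    width = len(str(n))
    data: dict[str, object] = {
        "patient_id": [f"P{i + 1:0{width}d}" for i in range(n)],
        "age": age, "sex": sex, "fev1_pct": fev1, "gold": gold,
        "pack_years": pack_years,
    }
    for inst in insts:
        data[f"{inst}_T0"] = np.round(B[inst], 2)
    for tp in FOLLOWUPS:
        for inst in insts:
            col = np.round(F[inst][tp], 2)
            data[f"{inst}_{tp}"] = np.where(observed[tp], col, np.nan)
    for tp in FOLLOWUPS:
        col = grc15[tp].astype(float)
        data[f"grc15_{tp}"] = np.where(observed[tp], col, np.nan)
    data["grc5_T5"] = np.where(observed["T5"], grc5, None)

    frame = pd.DataFrame(data)

    # a handful of incomplete discharge questionnaires (scores missing
    # even though the patient attended) and one missing discharge GRC
    for inst in insts:
        k = min(cfg.discharge_incomplete.get(inst, 0), n)
        if k:
            idx = rng.choice(n, size=k, replace=False)
            frame.loc[idx, f"{inst}_T1"] = np.nan
    if cfg.n_missing_grc15_t1:
        idx = rng.choice(n, size=min(cfg.n_missing_grc15_t1, n),
                         replace=False)
        frame.loc[idx, "grc15_T1"] = np.nan

    latent_cols: dict[str, object] = {"patient_id": data["patient_id"]}
    for inst in insts:
        for tp in FOLLOWUPS:
            latent_cols[f"delta_{inst}_{tp}"] = delta[inst][tp]
    for tp in FOLLOWUPS:
        latent_cols[f"grc15_{tp}"] = grc15[tp]
        latent_cols[f"comp_{tp}"] = comp[tp]
    latent_cols["grc5_code_T5"] = codes
    truth = SyntheticTruth(
        config=cfg,
        latent=pd.DataFrame(latent_cols),
        noise_scales={tp: calib[tp][0] for tp in FOLLOWUPS},
        comp_scales={tp: calib[tp][1] for tp in FOLLOWUPS},
    )
    cohort = LongitudinalCohort(frame, instruments)
    return cohort, truth


def subgroup_truth(
    cfg: GeneratorConfig,
    n: int = 150_000,
    seed: int = _TRUTH_SEED,
) -> dict[tuple[str, str, str], float]:
    """Asymptotic subgroup mean change per instrument x scheme x period.

    Runs the generator at large ``n`` (fixed truth seed, same
    data-generating law as any replicate of ``cfg``) and returns the
    mean change of the minimally-improved 15-point subgroup and the
    somewhat-better five-point subgroup.  These are the quantities an
    anchor-based MCID estimate targets.
    """
    big = replace(cfg, n_patients=n, seed=seed)
    _, truth = generate(big)
    lat = truth.latent
    out: dict[tuple[str, str, str], float] = {}
    for tp in FOLLOWUPS:
        g = lat[f"grc15_{tp}"].to_numpy()
        mask15 = (g == 2) | (g == 3)
        for inst in cfg.baseline_mean:
            out[(inst, "grc15", tp)] = float(
                lat.loc[mask15, f"delta_{inst}_{tp}"].mean())
    mask5 = lat["grc5_code_T5"].to_numpy() == 1  # somewhat better
    for inst in cfg.baseline_mean:
        out[(inst, "grc5", "T5")] = float(
            lat.loc[mask5, f"delta_{inst}_T5"].mean())
    return out


# ---------------------------------------------------------------------------
# Fixture registry

def _tiny12_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_patients=12, seed=7,
        dropout={"T1": 451, "T2": 451, "T3": 451, "T4": 451, "T5": 451},
        discharge_incomplete={}, n_missing_grc15_t1=0,
        n_calibration=5_000,
    )


def _cohort451_config() -> GeneratorConfig:
    return GeneratorConfig(seed=451)


def _null_config() -> GeneratorConfig:
    zero = {inst: {tp: 0.0 for tp in FOLLOWUPS}
            for inst in _default_baseline_mean()}
    return GeneratorConfig(effects=zero, seed=11)


FIXTURES = {
    "tiny12": _tiny12_config,
    "cohort451": _cohort451_config,
    "null": _null_config,
}


def make_fixture(
    name: str, path: str | Path | None = None
) -> tuple[LongitudinalCohort, SyntheticTruth]:
    """Deterministic named cohorts for tests and documentation.

    * ``tiny12`` — 12 patients, baseline + discharge only, complete data.
    * ``cohort451`` — full published-schedule cohort (451 patients,
      T0-T5, dropout 451/355/319/304/309 with twelve-month re-entry).
    * ``null`` — no treatment effect, for type-I-error experiments.
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    cohort, truth = generate(FIXTURES[name]())
    if name == "tiny12":
        keep = [c for c in cohort.data.columns
                if not any(c.endswith(tp) for tp in ("T2", "T3", "T4", "T5"))]
        cohort = LongitudinalCohort(cohort.data[keep], cohort.instruments)
    if path is not None:
        cohort.to_csv(path)
    return cohort, truth
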