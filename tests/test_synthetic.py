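"""Synthetic cohort generator: determinism, structure, self-targets."""
import numpy as np
import pandas as pd
import pytest

from mcidkit.comparison import icc_baseline_followup
from mcidkit.instruments import standardize
from mcidkit.pipeline import FOLLOWUPS
from mcidkit.synthetic import (
    FIXTURES,
    GeneratorConfig,
    generate,
    make_fixture,
    subgroup_truth,
)

INSTRUMENTS = ("CAT", "CCQ", "SGRQ")


def test_identical_config_and_seed_reproduce_identical_cohort():
    a, _ = generate(GeneratorConfig(n_patients=40, seed=5,
                                    n_calibration=3000))
    b, _ = generate(GeneratorConfig(n_patients=40, seed=5,
                                    n_calibration=3000))
    pd.testing.assert_frame_equal(a.data, b.data)


def test_different_seed_changes_cohort():
    a, _ = generate(GeneratorConfig(n_patients=40, seed=5,
                                    n_calibration=3000))
    b, _ = generate(GeneratorConfig(n_patients=40, seed=6,
                                    n_calibration=3000))
    assert not a.data.equals(b.data)


def test_scores_stay_within_instrument_ranges(default_cohort):
    cohort, _ = default_cohort
    for inst in INSTRUMENTS:
        hi = cohort.instruments[inst].scale_max
        for tp in ("T0",) + FOLLOWUPS:
            col = cohort.data[f"{inst}_{tp}"].dropna()
            assert ((col >= 0) & (col <= hi)).all()
    for tp in FOLLOWUPS:
        g = cohort.data[f"grc15_{tp}"].dropna()
        assert g.isin(range(-7, 8)).all()


def test_standardization_roundtrips(default_cohort):
    cohort, _ = default_cohort
    spec = cohort.instruments["CAT"]
    x = cohort.data["CAT_T0"].to_numpy()
    back = standardize(spec, x) * spec.scale_max / 100.0
    assert np.allclose(back, x)


def test_dropout_schedule_with_reentry(default_cohort):
    cohort, _ = default_cohort
    counts = {tp: int(cohort.data[f"grc15_{tp}"].notna().sum())
              for tp in FOLLOWUPS}
    # discharge GRC has one missing rating on top of full attendance
    assert counts == {"T1": 450, "T2": 355, "T3": 319, "T4": 304, "T5": 309}
    # re-entry: every nine-month completer is observed at twelve months
    t4 = cohort.data["grc15_T4"].notna()
    t5 = cohort.data["grc15_T5"].notna()
    assert (t4 & ~t5).sum() == 0
    assert (t5 & ~t4).sum() == 5


def test_discharge_incomplete_questionnaires(default_cohort):
    cohort, _ = default_cohort
    missing = {inst: int(cohort.data[f"{inst}_T1"].isna().sum())
               for inst in INSTRUMENTS}
    assert missing == {"CAT": 2, "CCQ": 1, "SGRQ": 4}


def test_zero_effect_perfect_dependency_edge_case():
    zero = {i: {tp: 0.0 for tp in FOLLOWUPS} for i in INSTRUMENTS}
    ones = {i: {tp: 1.0 for tp in FOLLOWUPS} for i in INSTRUMENTS}
    cfg = GeneratorConfig(n_patients=30, seed=2, effects=zero, icc=ones,
                          discharge_incomplete={}, n_missing_grc15_t1=0,
                          n_calibration=2000)
    cohort, truth = generate(cfg)
    for inst in INSTRUMENTS:
        deltas = cohort.data[f"{inst}_T1"] - cohort.data[f"{inst}_T0"]
        assert np.allclose(deltas.dropna(), 0.0)
    assert (cohort.data["grc15_T1"].dropna() == 0).all()
    lat = truth.latent
    assert not ((lat["grc15_T1"] == 2) | (lat["grc15_T1"] == 3)).any()


def test_infeasible_anchor_target_rejected():
    cfg = GeneratorConfig(
        n_patients=30, seed=0, n_calibration=2000,
        anchor_validity={tp: 0.999 for tp in FOLLOWUPS},
    )
    with pytest.raises(ValueError, match="infeasible|not reachable"):
        generate(cfg)


class TestSelfTargets:
    """Realised moments at n=5000 sit on the configured targets."""

    def test_baseline_means(self, big_cohort):
        cohort, _ = big_cohort
        cfg = GeneratorConfig()
        for inst in INSTRUMENTS:
            assert cohort.data[f"{inst}_T0"].mean() == pytest.approx(
                cfg.baseline_mean[inst], abs=0.2)

    def test_baseline_sds(self, big_cohort):
        cohort, _ = big_cohort
        cfg = GeneratorConfig()
        for inst in INSTRUMENTS:
            assert cohort.data[f"{inst}_T0"].std() == pytest.approx(
                cfg.baseline_sd[inst], abs=0.1 * cfg.baseline_sd[inst])

    def test_realized_icc_hits_target(self, big_cohort):
        cohort, _ = big_cohort
        cfg = GeneratorConfig()
        df = cohort.data
        for inst in INSTRUMENTS:
            for tp in FOLLOWUPS:
                m = df[f"{inst}_T0"].notna() & df[f"{inst}_{tp}"].notna()
                rho = icc_baseline_followup(
                    df.loc[m, f"{inst}_T0"], df.loc[m, f"{inst}_{tp}"],
                    form="icc3")
                assert rho == pytest.approx(cfg.icc[inst][tp], abs=0.05)

    def test_realized_anchor_correlation_hits_target(self, big_cohort):
        _, truth = big_cohort
        cfg = GeneratorConfig()
        lat = truth.latent
        for tp in FOLLOWUPS:
            r = np.corrcoef(lat[f"grc15_{tp}"], lat[f"comp_{tp}"])[0, 1]
            assert abs(r) == pytest.approx(cfg.anchor_validity[tp], abs=0.05)

    def test_anchor_correlation_is_negative(self, big_cohort):
        # positive GRC = improvement, negative change = improvement
        _, truth = big_cohort
        lat = truth.latent
        r = np.corrcoef(lat["grc15_T5"], lat["comp_T5"])[0, 1]
        assert r < 0


def test_subgroup_truth_is_negative_improvement():
    truth = subgroup_truth(GeneratorConfig(), n=20000)
    for (inst, scheme, tp), val in truth.items():
        assert val < 0, (inst, scheme, tp)


class TestFixtures:
    def test_tiny12_shape_and_determinism(self, tmp_path, tiny_cohort):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        make_fixture("tiny12", p1)
        make_fixture("tiny12", p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert tiny_cohort.n_patients == 12
        tps = {c.rsplit("_", 1)[-1] for c in tiny_cohort.data.columns
               if "_T" in c}
        assert tps == {"T0", "T1"}
        assert tiny_cohort.data.notna().all().all()

    def test_cohort451_schedule(self):
        cohort, _ = make_fixture("cohort451")
        assert cohort.n_patients == 451
        counts = [int(cohort.data[f"grc15_{tp}"].notna().sum())
                  for tp in FOLLOWUPS]
        assert counts == [450, 355, 319, 304, 309]

    def test_null_fixture_has_no_effect(self):
        cohort, truth = make_fixture("null")
        for inst in INSTRUMENTS:
            assert truth.config.effects[inst]["T5"] == 0.0
        deltas = cohort.data["CAT_T5"] - cohort.data["CAT_T0"]
        assert abs(deltas.mean()) < 1.0

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            make_fixture("nope")

    def test_registry_names(self):
        assert set(FIXTURES) == {"tiny12", "cohort451", "null"}
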