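"""Synthetic cohort generator: determinism, mechanism, and anchor recovery."""

import dataclasses

import numpy as np
import pytest

from renalperf import (
    GeneratorConfig,
    assign_aki_mechanism,
    compute_series,
    generate,
    generate_with_metadata,
    implied_aki_fraction,
    make_table1_fixture,
    stage_patient,
)
from renalperf.synthetic import DEFAULT_GROUP_MEDIANS, ConfigurationError


class TestConfig:
    def test_defaults_reproduce_anchor_medians(self):
        cfg = GeneratorConfig()
        assert cfg.group_pressure_medians[("noAKI", 0, "map_mmHg")] == 89
        assert cfg.group_pressure_medians[("AKI", 0, "map_mmHg")] == 82
        assert cfg.group_pressure_medians[("noAKI", 0, "pmean_mmHg")] == 9
        assert cfg.group_pressure_medians[("AKI", 0, "pmean_mmHg")] == 9

    @pytest.mark.parametrize(
        "bad",
        [
            {"p_ventilated": 1.5},
            {"n_patients": 0},
            {"ar_coefficient": 1.0},
            {"pressure_sd": {"map_mmHg": -1.0}},
            {"stage_weights": (0.5, 0.5)},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        cfg = dataclasses.replace(GeneratorConfig(), **bad)
        if "pressure_sd" in bad:
            cfg.pressure_sd.update(bad["pressure_sd"])
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestMechanism:
    def _rng(self):
        return np.random.default_rng(0)

    def test_below_threshold_always_aki(self):
        cfg = GeneratorConfig()
        assert assign_aki_mechanism(38.0, +20.0, cfg, self._rng()) == "AKI"

    def test_above_and_rising_never_aki(self):
        cfg = GeneratorConfig()
        assert assign_aki_mechanism(55.0, +9.0, cfg, self._rng()) == "noAKI"

    def test_above_declining_with_degenerate_probability(self):
        cfg = dataclasses.replace(GeneratorConfig(), p_aki_given_above_declining=1.0)
        assert assign_aki_mechanism(55.0, -4.0, cfg, self._rng()) == "AKI"
        cfg0 = dataclasses.replace(GeneratorConfig(), p_aki_given_above_declining=0.0)
        assert assign_aki_mechanism(55.0, -4.0, cfg0, self._rng()) == "noAKI"

    def test_nonfinite_rpp_rejected(self):
        with pytest.raises(ValueError):
            assign_aki_mechanism(float("nan"), 0.0, GeneratorConfig(), self._rng())


class TestGenerate:
    def test_patient_count(self, default_cohort):
        assert len(default_cohort) == 84

    def test_same_seed_identical_different_seed_differs(self):
        a = generate(GeneratorConfig(seed=5))
        b = generate(GeneratorConfig(seed=5))
        c = generate(GeneratorConfig(seed=6))
        assert [dataclasses.asdict(p) for p in a] == [dataclasses.asdict(p) for p in b]
        assert [dataclasses.asdict(p) for p in a] != [dataclasses.asdict(p) for p in c]

    def test_cohort_passes_validation(self, default_cohort):
        default_cohort.validate()

    def test_pmean_only_for_ventilated(self, default_cohort):
        for p in default_cohort:
            for obs in p.pressures:
                if not p.ventilated:
                    assert obs.pmean_mmHg is None
                else:
                    assert obs.pmean_mmHg is not None

    def test_admission_to_12h_panels_complete(self, default_cohort):
        for p in default_cohort:
            for t in (0, 6, 12):
                assert p.observation(t) is not None

    def test_forcing_all_below_threshold_yields_all_aki(self):
        cfg = GeneratorConfig(seed=3, rpp_threshold_mmHg=500.0)
        cohort = generate(cfg)
        for p in cohort:
            assert stage_patient(p).stage >= 1

    def test_mechanism_consistency_from_recomputed_pressures(self, default_result):
        """No above-threshold riser is AKI; no below-threshold patient is AKI-free."""
        meta = default_result.metadata.set_index("patient_id")
        for p in default_result.cohort:
            series = compute_series(p, "EFFECTIVE_RPP", pmean_policy="zero")
            rpp0, delta = series.value(0), series.delta(0, 12)
            final = meta.loc[p.patient_id, "final_group"]
            if rpp0 < 40.7:
                assert final == "AKI"
            elif delta > 0:
                assert final == "noAKI"


class TestAnchorRecovery:
    def test_group_medians_recovered_at_large_n(self):
        """Sample medians converge to configured medians (n = 2000, +-1.5 mmHg).

        The 12 h MAP is checked against the configured median plus the
        documented trajectory steering offset; everything else against the
        configured median directly.
        """
        from renalperf.synthetic import _map12_adjustment

        cfg = GeneratorConfig(n_patients=2000, seed=17, dropout_hazard_24h={"noAKI": 0, "AKI": 0},
                              dropout_hazard_48h={"noAKI": 0, "AKI": 0})
        res = generate_with_metadata(cfg)
        meta = res.metadata.set_index("patient_id")
        values: dict[tuple, list] = {}
        map12: dict[tuple, list] = {}
        for p in res.cohort:
            g = meta.loc[p.patient_id, "intended_group"]
            for obs in p.pressures:
                for f in ("map_mmHg", "iap_mmHg", "cvp_mmHg", "pmean_mmHg"):
                    v = getattr(obs, f)
                    if v is None:
                        continue
                    if f == "map_mmHg" and obs.time_h == 12:
                        map12.setdefault((g, p.ventilated), []).append(v)
                    else:
                        values.setdefault((g, obs.time_h, f), []).append(v)
        for (g, t, f), vals in values.items():
            assert np.median(vals) == pytest.approx(
                cfg.group_pressure_medians[(g, t, f)], abs=1.5
            ), (g, t, f)
        # the 12 h MAP carries the trajectory steering offset; its cells are
        # split by ventilation (the offset depends on it), so smaller
        for (g, vent), vals in map12.items():
            expected = cfg.group_pressure_medians[(g, 12, "map_mmHg")] + _map12_adjustment(
                cfg, g, vent
            )
            assert np.median(vals) == pytest.approx(expected, abs=2.5), (g, vent)

    def test_aki_fraction_within_binomial_envelope(self):
        """Pooled AKI fraction over many cohorts sits in the 99% envelope
        of the config-implied probability."""
        cfg = GeneratorConfig()
        p_implied = implied_aki_fraction(cfg, n_mc=8000, seed=999)
        n_cohorts, n = 30, cfg.n_patients
        total_aki = 0
        for s in range(n_cohorts):
            meta = generate_with_metadata(dataclasses.replace(cfg, seed=1000 + s)).metadata
            total_aki += (meta.final_group == "AKI").sum()
        total = n_cohorts * n
        se = np.sqrt(p_implied * (1 - p_implied) / total + p_implied * (1 - p_implied) / 8000)
        assert abs(total_aki / total - p_implied) < 2.576 * se + 0.01


def test_table1_fixture_counts():
    fx = make_table1_fixture()
    assert fx["group_sizes"] == {"noAKI": 45, "AKI": 39}
    assert sum(fx["surgery_counts"].values()) == 84
    assert fx["sepsis"]["AKI"] == 16
    assert fx["ventilated"] == {"noAKI": 15, "AKI": 25}
    assert fx["icu_death"] == {"noAKI": 2, "AKI": 9}
    assert fx["hospital_death"] == {"noAKI": 5, "AKI": 13}
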