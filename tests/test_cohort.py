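"""Synthetic cohort generator: determinism, calibration, design structure."""

import numpy as np
import pandas as pd
import pytest

from gwinet import (
    CohortConfig,
    Effect,
    MeasureSpec,
    StandardCurve,
    generate_cohort,
    generate_duplicate_wells,
    generate_latent_network,
    invert_curve,
    spearman_to_pearson,
)
from gwinet.cohort import CohortConfigError, config_from_yaml, config_to_yaml


def test_seed_determinism(small_config):
    """Identical config + seed produce bit-identical tables."""
    a = generate_cohort(small_config)
    b = generate_cohort(small_config)
    pd.testing.assert_frame_equal(a.data, b.data)
    pd.testing.assert_frame_equal(a.subjects, b.subjects)


def test_different_seeds_differ(small_config, small_catalog):
    other = CohortConfig(**{**small_config.__dict__, "seed": 43})
    a = generate_cohort(small_config)
    b = generate_cohort(other)
    assert not np.allclose(
        a.data["value"].to_numpy(), b.data["value"].to_numpy(), equal_nan=True
    )


def test_il15_group_means_near_programmed_targets(small_catalog):
    """IL-15 means 0.24/0.15/0.22 recovered within 3 SE at n=(44,29,47)."""
    config = CohortConfig(
        measure_catalog=small_catalog,
        group_sizes={"HC": 44, "GWI_L": 29, "GWI_H": 47},
        effect_map={
            "IL-15": {
                "GWI_L": {"T0": Effect((0.15 - 0.24) / 0.199, 0.108 / 0.199)},
                "GWI_H": {"T0": Effect((0.22 - 0.24) / 0.199, 0.206 / 0.199)},
            }
        },
        missing_rate=0.0,
        seed=7,
    )
    cohort = generate_cohort(config)
    values = cohort.group_values("IL-15", "T0")
    targets = {"HC": (0.24, 0.199), "GWI_L": (0.15, 0.108), "GWI_H": (0.22, 0.206)}
    for group, (mean, sd) in targets.items():
        vals = values[group]
        se = sd / np.sqrt(vals.size)
        assert abs(vals.mean() - mean) < 3 * se, group


def test_zero_missing_rate_yields_complete_table(small_config):
    cohort = generate_cohort(small_config)
    assert cohort.data["value"].notna().all()


def test_missing_rate_produces_missing_cells(small_config):
    config = CohortConfig(**{**small_config.__dict__, "missing_rate": 0.2})
    cohort = generate_cohort(config)
    frac = cohort.data["value"].isna().mean()
    assert 0.1 < frac < 0.3


def test_marginal_calibration_large_n():
    """At n=10,000 per group each measure's mean/SD is within 1% of target."""
    config = CohortConfig(
        measure_catalog=[
            MeasureSpec("m1", "cytokine", 10.0, 2.0, panel="both"),
            MeasureSpec("m2", "hormone", 100.0, 25.0),
        ],
        group_sizes={"HC": 10_000, "GWI_L": 2, "GWI_H": 2},
        timepoints=("T0",),
        missing_rate=0.0,
        seed=11,
    )
    cohort = generate_cohort(config)
    for name, mean, sd in (("m1", 10.0, 2.0), ("m2", 100.0, 25.0)):
        vals = cohort.group_values(name, "T0")["HC"]
        assert abs(vals.mean() - mean) / mean < 0.01
        assert abs(vals.std(ddof=1) - sd) / sd < 0.01


def test_network_calibration_large_n():
    """Sample Spearman correlation converges to the latent target."""
    target = 0.5
    latent = np.array([[1.0, target], [target, 1.0]])
    config = CohortConfig(
        measure_catalog=[
            MeasureSpec("a", "cytokine", 0.0, 1.0, panel="both"),
            MeasureSpec("b", "flow", 0.0, 1.0),
        ],
        group_sizes={"HC": 5000, "GWI_L": 2, "GWI_H": 2},
        timepoints=("T0",),
        latent_network={"HC": latent},
        missing_rate=0.0,
        seed=5,
    )
    cohort = generate_cohort(config)
    wide = cohort.wide("T0", group="HC")
    rho = wide.corr(method="spearman").loc["a", "b"]
    assert abs(rho - target) < 0.05


def test_rest_only_subjects_have_no_exercise_timepoints(small_config):
    cohort = generate_cohort(small_config)
    rest_ids = set(
        cohort.subjects.loc[
            cohort.subjects["site"] == "rest_only_site", "subject_id"
        ]
    )
    assert rest_ids  # site split creates some
    later = cohort.data[cohort.data["timepoint"].isin(["T1", "T2"])]
    assert rest_ids.isdisjoint(set(later["subject_id"]))


def test_symptoms_constant_across_timepoints(small_config):
    cohort = generate_cohort(small_config)
    sym = cohort.data[cohort.data["family"] == "symptom"]
    per_subject = sym.groupby(["subject_id", "measure"])["value"].nunique()
    assert (per_subject == 1).all()


def test_dts_respects_group_side(small_config):
    cohort = generate_cohort(small_config)
    subs = cohort.subjects[cohort.subjects["dts_total"].notna()]
    high = subs[subs["group"] == "GWI_H"]["dts_total"].astype(int)
    low = subs[subs["group"] != "GWI_H"]["dts_total"].astype(int)
    assert (high >= 70).all()
    assert (low < 70).all()


def test_group_size_below_two_rejected(small_catalog):
    config = CohortConfig(
        measure_catalog=small_catalog, group_sizes={"HC": 1, "GWI_L": 5, "GWI_H": 5}
    )
    with pytest.raises(CohortConfigError, match="at least 2"):
        generate_cohort(config)


def test_non_psd_latent_rejected(small_catalog):
    bad = np.array(
        [[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]]
    )  # eigenvalues include a negative one
    config = CohortConfig(
        measure_catalog=small_catalog,
        group_sizes={"HC": 5, "GWI_L": 5, "GWI_H": 5},
        latent_network={"HC": bad},
    )
    with pytest.raises(CohortConfigError, match="positive semi-definite"):
        generate_cohort(config)


def test_config_yaml_round_trip(tmp_path, small_config):
    path = tmp_path / "config.yaml"
    config_to_yaml(small_config, path)
    loaded = config_from_yaml(path)
    a = generate_cohort(small_config)
    b = generate_cohort(loaded)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_cohort_csv_round_trip(tmp_path, small_config):
    cohort = generate_cohort(small_config)
    path = tmp_path / "cohort.csv"
    cohort.write_csv(path)
    loaded = type(cohort).read_csv(path)
    pd.testing.assert_frame_equal(
        cohort.data.reset_index(drop=True),
        loaded.data,
        check_dtype=False,
    )


class TestGenerateLatentNetwork:
    def test_zero_edges_gives_identity(self):
        mat = generate_latent_network(5, 0, seed=1)
        assert np.array_equal(mat, np.eye(5))

    def test_three_node_single_edge_is_psd(self):
        mat = generate_latent_network(3, 1, (0.5, 0.5), seed=2)
        offdiag = mat[np.triu_indices(3, 1)]
        assert sorted(np.round(np.abs(offdiag), 6)) == [0.0, 0.0, 0.5]
        assert np.linalg.eigvalsh(mat).min() >= -1e-10

    def test_reproducible(self):
        a = generate_latent_network(8, 10, (0.3, 0.6), seed=3)
        b = generate_latent_network(8, 10, (0.3, 0.6), seed=3)
        assert np.array_equal(a, b)

    def test_too_many_edges_rejected(self):
        with pytest.raises(CohortConfigError, match="exceeds"):
            generate_latent_network(3, 4)

    def test_spearman_pearson_map(self):
        # exact at 0 and 1; monotone increasing in between
        assert spearman_to_pearson(0.0) == 0.0
        assert np.isclose(spearman_to_pearson(1.0), 1.0)
        grid = spearman_to_pearson(np.linspace(-1, 1, 21))
        assert np.all(np.diff(grid) > 0)


class TestDuplicateWells:
    def test_zero_cv_gives_noiseless_signal(self, fivepl_curve):
        wells = generate_duplicate_wells(100.0, fivepl_curve, 0.0, seed=1)
        expected = fivepl_curve.evaluate(100.0)
        assert np.allclose(wells, expected)

    def test_monte_carlo_back_calculation_unbiased(self, fivepl_curve):
        """cv=0.1, 1000 replicates: mean back-calculated conc within 2%."""
        rng = np.random.default_rng(8)
        concs = []
        for _ in range(1000):
            wells = generate_duplicate_wells(100.0, fivepl_curve, 0.1, seed=rng)
            concs.extend(invert_curve(fivepl_curve, w) for w in wells)
        assert abs(np.mean(concs) - 100.0) / 100.0 < 0.02

    def test_zero_conc_signals_near_floor(self):
        """On a rising curve (b < 0), zero concentration sits at the floor d."""
        curve = StandardCurve(
            model="logistic5p",
            params={"a": 30000.0, "d": 50.0, "c": 100.0, "b": -1.2, "g": 1.0},
            calibrated_range=(0.0, 1000.0),
        )
        wells = generate_duplicate_wells(0.0, curve, 0.01, seed=2)
        assert np.all(np.abs(wells - 50.0) < 0.05 * (30000.0 - 50.0))

    def test_negative_cv_rejected(self, fivepl_curve):
        with pytest.raises(ValueError, match="cv"):
            generate_duplicate_wells(100.0, fivepl_curve, -0.1)
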