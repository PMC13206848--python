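"""Desynchronization index: geometry, brute-force equivalence, PC1, model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import suvr_profiles
from petdesync import (DesynchronizationModel, bootstrap_pair_fits,
                       composite_pc1, compute_di, compute_suvr,
                       perpendicular_distance)


class TestPerpendicularDistance:
    def test_known_values(self):
        assert perpendicular_distance((3, 3), (1, 0)) == 0.0
        assert perpendicular_distance((0, 1), (1, 0)) == pytest.approx(
            1 / np.sqrt(2), abs=1e-12)
        assert perpendicular_distance((2, 5), (0, 3)) == pytest.approx(2.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            perpendicular_distance((np.nan, 0), (1, 0))
        with pytest.raises(ValueError):
            perpendicular_distance((0, 0), (np.inf, 0))

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(-20, 20), st.floats(-20, 20), st.floats(-5, 5),
           st.floats(-20, 20))
    def test_nonnegative_and_zero_on_line(self, x, t, b, a):
        """d >= 0 everywhere and exactly 0 for points on the line."""
        assert perpendicular_distance((x, t), (b, a)) >= 0
        assert perpendicular_distance((x, b * x + a), (b, a)) == pytest.approx(
            0.0, abs=1e-9)


def _brute_force_di(profile: dict[str, float], fits) -> dict[str, float]:
    """Independent oracle: double loop over all pairs, summing distances."""
    vois = list(fits.vois)
    di = {v: 0.0 for v in vois}
    for p, (i, j) in enumerate(fits.pairs):
        d = perpendicular_distance(
            (profile[vois[i]], profile[vois[j]]),
            (fits.consensus_slope[p], fits.consensus_intercept[p]))
        di[vois[i]] += d
        di[vois[j]] += d
    return di


@pytest.fixture(scope="module")
def ensemble():
    rng = np.random.default_rng(0)
    base = rng.uniform(1, 2, size=5)
    data = {f"V{k}": (base * rng.uniform(0.8, 1.2)
                      + rng.normal(0, 0.05, 5)).tolist() for k in range(5)}
    table = suvr_profiles(data)
    fits = bootstrap_pair_fits(table, [f"s{i}" for i in range(5)],
                               sorted(data), B=30, seed=1)
    return table, fits


class TestComputeDI:
    def test_brute_force_equivalence(self, ensemble):
        """compute_di equals the pairwise double-loop oracle exactly (V<=6)."""
        table, fits = ensemble
        wide = table.pivot_table(index="subject_id", columns="voi",
                                 values="value")
        di, skipped = compute_di(wide, fits)
        assert not skipped
        for sid in wide.index:
            oracle = _brute_force_di(wide.loc[sid].to_dict(), fits)
            for v in fits.vois:
                assert di.loc[sid, v] == pytest.approx(oracle[v], abs=1e-12)

    def test_on_fit_subject_scores_zero(self):
        """A subject lying on every consensus line has DI = 0 in all VOIs."""
        x = [1.0, 2.0, 3.0, 4.0]
        table = suvr_profiles({"A": x, "B": [2 * v for v in x],
                               "C": [v + 1 for v in x]})
        fits = bootstrap_pair_fits(table, [f"s{i}" for i in range(4)],
                                   ["A", "B", "C"], B=20, seed=0)
        probe = pd.DataFrame({"A": [2.5], "B": [5.0], "C": [3.5]},
                             index=["probe"])
        di, _ = compute_di(probe, fits)
        assert np.allclose(di.to_numpy(), 0.0, atol=1e-9)

    def test_single_perturbation_structure(self):
        """Perturbing one VOI: DI_v (v != k) is that single pair distance,
        DI_k is their sum, and total DI is twice the summed pair distances."""
        x = [1.0, 2.0, 3.0, 4.0]
        table = suvr_profiles({"A": x, "B": [2 * v for v in x],
                               "C": [v + 1 for v in x],
                               "D": [3 * v - 1 for v in x]})
        vois = ["A", "B", "C", "D"]
        fits = bootstrap_pair_fits(table, [f"s{i}" for i in range(4)], vois,
                                   B=20, seed=0)
        probe = pd.DataFrame({"A": [2.5], "B": [5.0 + 0.7], "C": [3.5],
                              "D": [6.5]}, index=["probe"])
        di, _ = compute_di(probe, fits)
        oracle = _brute_force_di(probe.loc["probe"].to_dict(), fits)
        for v in vois:
            assert di.loc["probe", v] == pytest.approx(oracle[v], abs=1e-12)
        others = [di.loc["probe", v] for v in ("A", "C", "D")]
        assert di.loc["probe", "B"] == pytest.approx(sum(others), abs=1e-12)
        pair_total = sum(
            perpendicular_distance(
                (probe.iloc[0][vois[i]], probe.iloc[0][vois[j]]),
                (fits.consensus_slope[p], fits.consensus_intercept[p]))
            for p, (i, j) in enumerate(fits.pairs))
        assert di.loc["probe"].sum() == pytest.approx(2 * pair_total, abs=1e-12)

    def test_missing_voi_skipped_with_report(self, ensemble):
        table, fits = ensemble
        wide = table.pivot_table(index="subject_id", columns="voi",
                                 values="value")
        wide.loc["s1", "V2"] = np.nan
        di, skipped = compute_di(wide, fits)
        assert [s["subject_id"] for s in skipped] == ["s1"]
        assert "V2" in skipped[0]["missing_vois"]
        assert "s1" not in di.index and len(di) == 4

    def test_per_replicate_flag_changes_but_correlates(self, ensemble):
        table, _ = ensemble
        # stable replicate averages need a non-trivial B
        vois = sorted(table["voi"].unique())
        fits = bootstrap_pair_fits(table, [f"s{i}" for i in range(5)], vois,
                                   B=500, seed=1)
        wide = table.pivot_table(index="subject_id", columns="voi",
                                 values="value")
        d_cons, _ = compute_di(wide, fits)
        d_rep, _ = compute_di(wide, fits, per_replicate=True)
        assert not np.allclose(d_cons, d_rep)
        # the two variants measure the same deviation structure
        c = np.corrcoef(d_cons.to_numpy().ravel(), d_rep.to_numpy().ravel())
        assert c[0, 1] > 0.9


class TestCompositePC1:
    def test_single_constituent(self):
        di = pd.DataFrame({"A": [0.0, 1.0, 2.0, 5.0], "B": [1, 1, 2, 0]},
                          index=list("wxyz"))
        scores, ev = composite_pc1(di, ["A"])
        assert ev == 1.0
        std = (di["A"] - di["A"].mean()) / di["A"].std(ddof=1)
        assert np.allclose(scores, std)

    def test_rank_one_pair(self):
        """DI matrix [[0,0],[1,2],[2,4]]: EV = 1, scores follow [-, 0, +]."""
        di = pd.DataFrame({"A": [0.0, 1.0, 2.0], "B": [0.0, 2.0, 4.0]},
                          index=list("pqr"))
        scores, ev = composite_pc1(di, ["A", "B"])
        assert ev == pytest.approx(1.0)
        assert scores["p"] < 0 and scores["r"] > 0
        assert scores["q"] == pytest.approx(0.0, abs=1e-12)
        assert scores["r"] == pytest.approx(-scores["p"], abs=1e-9)

    def test_sign_oriented_toward_mean_di(self, small_cohort, atlas):
        suvr = compute_suvr(
            small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"],
            "brainstem").table
        res = DesynchronizationModel(suvr, atlas).fit(B=60, seed=0)
        for name in res.composites.columns:
            members = [v for v in atlas.composites[name]]
            c = np.corrcoef(res.composites[name],
                            res.di[members].mean(axis=1))[0, 1]
            assert c > 0

    def test_guards(self):
        di = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            composite_pc1(di, ["A", "B"])
        with pytest.raises(ValueError, match=">=3"):
            composite_pc1(di.iloc[:2], ["B"])
        with pytest.raises(ValueError, match="absent"):
            composite_pc1(di, ["Z"])


class TestModel:
    def test_control_subjects_score_lower_than_desynchronized(self):
        """In-sample control DI is positive but below delta >= 0.5 arms."""
        from petdesync import default_atlas, default_config, generate_cohort
        from petdesync.atlas import CORTICAL_VOIS
        wins = 0
        for seed in range(10):
            cfg = default_config(
                seed=100 + seed, timepoints=(10.0,),
                n_per_arm={"WT PL/PL": 30, "KI Ab/PL": 30},
                genotype_slope={v: 0.0 for v in default_config().vois},
                desync_delta={"WT PL/PL": 0.0, "KI Ab/PL": 0.5},
                missing_rate={}, behavior_beta={})
            cohort = generate_cohort(cfg)
            suvr = compute_suvr(
                cohort.uptake[cohort.uptake["tracer"] == "TSPO"],
                "brainstem").table
            model = DesynchronizationModel(suvr, default_atlas())
            res = model.fit(B=200, seed=seed)
            mdi = res.di[list(CORTICAL_VOIS)].mean(axis=1)
            ctrl = mdi[mdi.index.str.startswith("WT")]
            desy = mdi[mdi.index.str.startswith("KI")]
            assert ctrl.min() > 0
            wins += desy.mean() > ctrl.mean()
        assert wins >= 9

    def test_summary_mentions_fit_settings(self, small_cohort, atlas):
        suvr = compute_suvr(
            small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"],
            "brainstem").table
        res = DesynchronizationModel(suvr, atlas).fit(B=25, seed=3)
        text = res.summary()
        assert "B=25" in text and "seed=3" in text
        assert "cortex" in text and "EHA" in text
        assert res.di_normalized.equals(res.di / (len(atlas.target_vois) - 1))
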