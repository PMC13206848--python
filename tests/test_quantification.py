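"""Quantification chain: %ID arithmetic, effect-size screen, SUVR, z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from petdesync import (cohen_d, compute_percent_id, compute_suvr,
                       compute_zscores, default_atlas, default_config,
                       extract_voi_means, generate_cohort,
                       select_pseudo_reference)


class TestPercentID:
    def test_arithmetic(self):
        assert compute_percent_id(0.8, 80.0) == pytest.approx(1.0)
        assert compute_percent_id(0.0, 80.0) == 0.0

    def test_guards(self):
        with pytest.raises(ValueError):
            compute_percent_id(1.0, 0.0)
        with pytest.raises(ValueError):
            compute_percent_id(-0.1, 10.0)


class TestCohenD:
    def test_known_values(self):
        assert cohen_d([1, 2, 3], [1, 2, 3]) == 0.0
        # means 3 vs 1, each variance 2 -> pooled sd sqrt(2), d = 2/sqrt(2)
        assert cohen_d([2, 4], [0, 2]) == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_guards(self):
        with pytest.raises(ValueError):
            cohen_d([1], [1, 2])
        with pytest.raises(ValueError):
            cohen_d([5, 5, 5], [5, 5, 5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.floats(-100, 100), st.floats(0.1, 20))
    def test_invariances(self, a, b, shift, scale):
        """Antisymmetry, shift invariance, and scale invariance of d."""
        a, b = np.asarray(a), np.asarray(b)
        if a.var(ddof=1) + b.var(ddof=1) == 0:
            return
        d = cohen_d(a, b)
        assert cohen_d(b, a) == pytest.approx(-d, rel=1e-9, abs=1e-12)
        assert cohen_d(a + shift, b + shift) == pytest.approx(d, rel=1e-6, abs=1e-9)
        assert cohen_d(a * scale, b * scale) == pytest.approx(d, rel=1e-6, abs=1e-9)


class TestPseudoReferenceScreen:
    def test_tie_breaks_lexicographic(self, atlas):
        rows = []
        for i in range(4):
            for g in ("WT", "KI"):
                for v in atlas.all_vois:
                    rows.append((f"{g}{i}", g, "PL/PL", 10.0, "TSPO", v,
                                 1.0 + i, "PCT_ID"))
        table = pd.DataFrame(rows, columns=["subject_id", "genotype", "arm",
                                            "age_months", "tracer", "voi",
                                            "value", "unit"])
        report = select_pseudo_reference(table, atlas)
        assert (report.effects["d"] == 0).all()
        assert report.selected_reference == min(atlas.all_vois)

    def test_singleton_candidate(self, small_cohort, atlas):
        tspo = small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"]
        rep = select_pseudo_reference(tspo, atlas,
                                      candidates=["periaqueductal_gray"])
        assert rep.selected_reference == "periaqueductal_gray"

    def test_missing_candidate_rejected(self, small_cohort, atlas):
        tspo = small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"]
        with pytest.raises(ValueError, match="absent"):
            select_pseudo_reference(tspo, atlas, candidates=["no_such_voi"])

    def test_null_voi_recovered(self):
        """With an effect everywhere but the brainstem, the screen finds it."""
        cfg = default_config(
            seed=3, timepoints=(10.0,),
            n_per_arm={"WT PL/PL": 25, "KI PL/PL": 25}, missing_rate={})
        cfg.genotype_slope = dict(cfg.genotype_slope)
        cfg.genotype_slope["periaqueductal_gray"] = \
            0.5 * cfg.base_mean["periaqueductal_gray"] / 5.0
        cohort = generate_cohort(cfg)
        rep = select_pseudo_reference(
            cohort.uptake[cohort.uptake["tracer"] == "TSPO"], default_atlas())
        assert rep.selected_reference == "brainstem"


class TestSUVR:
    def test_arithmetic_and_reference_unity(self, small_cohort):
        tspo = small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"]
        res = compute_suvr(tspo, "brainstem")
        ref_rows = res.table[res.table["voi"] == "brainstem"]
        assert (ref_rows["value"] == 1.0).all()
        # spot-check one subject: SUVR = raw / raw_reference
        sid = tspo["subject_id"].iloc[0]
        raw = tspo[tspo["subject_id"] == sid].set_index("voi")["value"]
        out = res.table[res.table["subject_id"] == sid].set_index("voi")["value"]
        v = "hippocampus_l"
        assert out[v] == pytest.approx(raw[v] / raw["brainstem"], rel=1e-12)

    def test_scale_invariance(self, small_cohort):
        """Multiplying a scan's %ID by c > 0 leaves its SUVR unchanged."""
        tspo = small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"].copy()
        base = compute_suvr(tspo, "brainstem").table
        sid = tspo["subject_id"].iloc[0]
        tspo.loc[tspo["subject_id"] == sid, "value"] *= 3.7
        rescaled = compute_suvr(tspo, "brainstem").table
        a = base[base["subject_id"] == sid].set_index("voi")["value"]
        b = rescaled[rescaled["subject_id"] == sid].set_index("voi")["value"]
        assert np.allclose(a, b, rtol=1e-12)

    def test_missing_reference_reported_not_dropped(self, small_cohort):
        tspo = small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"]
        sid = tspo["subject_id"].iloc[0]
        broken = tspo[~((tspo["subject_id"] == sid)
                        & (tspo["voi"] == "brainstem"))]
        res = compute_suvr(broken, "brainstem")
        assert any(e["subject_id"] == sid for e in res.excluded_scans)
        assert sid not in set(res.table["subject_id"])
        assert set(broken["subject_id"]) - {sid} == set(res.table["subject_id"])


class TestZScores:
    def test_derived_value(self, atlas):
        """4 controls [1,2,3,4] and a probe of 4 -> z = 1.5/1.2910 = 1.1619."""
        from conftest import suvr_profiles
        table = suvr_profiles({"hippocampus_l": [1.0, 2.0, 3.0, 4.0, 4.0],
                               "amygdala_l": [1.0, 2.0, 3.0, 4.0, 2.5]})
        z = compute_zscores(table, ["s0", "s1", "s2", "s3"])
        probe = z[z["subject_id"] == "s4"].set_index("voi")["value"]
        assert probe["hippocampus_l"] == pytest.approx(1.161895, abs=1e-6)
        assert probe["amygdala_l"] == pytest.approx(0.0, abs=1e-12)

    def test_controls_are_standardized(self, small_cohort):
        tspo = small_cohort.uptake[small_cohort.uptake["tracer"] == "TSPO"]
        suvr = compute_suvr(tspo, "brainstem").table
        suvr = suvr[suvr["voi"] != "brainstem"]
        wt = sorted(suvr.loc[suvr["genotype"] == "WT", "subject_id"].unique())
        z = compute_zscores(suvr, wt)
        ctrl = z[z["subject_id"].isin(wt)]
        stats = ctrl.groupby("voi")["value"].agg(["mean", "std"])
        assert np.allclose(stats["mean"], 0.0, atol=1e-12)
        assert np.allclose(stats["std"], 1.0, atol=1e-12)

    def test_zero_control_sd_rejected(self):
        from conftest import suvr_profiles
        table = suvr_profiles({"hippocampus_l": [2.0, 2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="zero control SD"):
            compute_zscores(table, ["s0", "s1", "s2", "s3"])


class TestVOIExtraction:
    def test_means_and_guards(self, atlas):
        labels = np.zeros((5, 5, 2), dtype=int)
        img = np.zeros((5, 5, 2))
        for i, (voi, lab) in enumerate(atlas.labels.items()):
            labels[i % 5, i // 5, 0] = lab
            img[i % 5, i // 5, 0] = float(i)
        means = extract_voi_means(img, labels, atlas)
        assert means[list(atlas.labels)[3]] == pytest.approx(3.0)
        # two-voxel label averages its voxels
        voi0, lab0 = next(iter(atlas.labels.items()))
        labels[0, 0, 1] = lab0
        img[0, 0, 1] = 2.0
        means = extract_voi_means(img, labels, atlas)
        assert means[voi0] == pytest.approx(1.0)  # mean of 0 and 2
        with pytest.raises(ValueError, match="shape"):
            extract_voi_means(img[:2], labels, atlas)
        labels[labels == lab0] = 0
        with pytest.raises(ValueError, match=voi0):
            extract_voi_means(img, labels, atlas)

    def test_nifti_roundtrip(self, atlas, tmp_path):
        """NIfTI image + label volume on disk yield the same regional means."""
        import nibabel as nib
        rng = np.random.default_rng(4)
        labels = np.zeros((5, 5, 2), dtype=np.int16)
        for i, lab in enumerate(atlas.labels.values()):
            labels[i % 5, i // 5, 0] = lab
        img = rng.uniform(0.2, 1.5, size=(5, 5, 2))
        ipath, lpath = tmp_path / "img.nii", tmp_path / "lab.nii"
        nib.save(nib.Nifti1Image(img, np.eye(4)), ipath)
        nib.save(nib.Nifti1Image(labels, np.eye(4)), lpath)
        from petdesync import extract_voi_means_nifti
        means = extract_voi_means_nifti(ipath, lpath, atlas)
        direct = extract_voi_means(img, labels, atlas)
        assert means.keys() == direct.keys()
        for v in means:
            assert means[v] == pytest.approx(direct[v], rel=1e-6)

    def test_uniform_image(self, atlas):
        labels = np.zeros((6, 6, 1), dtype=int)
        for i, lab in enumerate(atlas.labels.values()):
            labels[i % 6, i // 6, 0] = lab
        img = np.full((6, 6, 1), 3.14)
        means = extract_voi_means(img, labels, atlas)
        assert all(m == pytest.approx(3.14) for m in means.values())
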