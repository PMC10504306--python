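"""MPM-based extraction, normality screen, t-tests and the study tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from facialdti import phantom
from facialdti.dtifit import ScalarMaps, cylinder_scalars, eigendecompose, \
    fit_tensor, scalar_maps
from facialdti.groupstats import (INDEXES, build_table_healthy,
                                  build_table_patient, build_table_pooled,
                                  build_tables, extract_indices, ks_normality,
                                  p_from_t, paired_ttest, unpaired_ttest)
from facialdti.mpm import MaxProbabilityMap


def _mpm_from_labels(labels):
    labels = np.asarray(labels, np.uint8)
    support = (labels > 0).astype(np.uint16)
    return MaxProbabilityMap(labels=labels, support=support, n_subjects=1)


def _uniform_scalars(shape, fa=0.5, md=1e-3, ad=1.2e-3, rd=0.9e-3):
    return ScalarMaps(fa=np.full(shape, fa), md=np.full(shape, md),
                      ad=np.full(shape, ad), rd=np.full(shape, rd))


def measurement_frame(manifest, mpm_name):
    """Long-format measurements from realized truth diffusivities."""
    rows = []
    for _, r in manifest.iterrows():
        for side in ("left", "right"):
            vals = cylinder_scalars(r[f"ad_{side}"], r[f"rd_{side}"])
            if r["group"] == "patient" and r["affected_side"] in ("left", "right"):
                role = "affected" if side == r["affected_side"] else "healthy_side"
            else:
                role = side
            rows.append({"subject_id": r["subject_id"], "group": r["group"],
                         "mpm": mpm_name, "side": side, "role": role, **vals})
    return pd.DataFrame(rows)


class TestExtract:
    def test_uniform_volume_mean(self):
        labels = np.zeros((4, 4, 4), np.uint8)
        labels[1, 1, 1] = 1
        labels[2, 2, 2] = 2
        df = extract_indices(_uniform_scalars((4, 4, 4)), _mpm_from_labels(labels),
                             "s1", "healthy", mpm_name="m")
        assert np.allclose(df["fa"], 0.5)
        assert set(df["role"]) == {"left", "right"}

    def test_two_voxel_label_mean(self):
        labels = np.zeros((3, 3, 3), np.uint8)
        labels[0, 0, 0] = 1
        labels[1, 0, 0] = 1
        labels[2, 2, 2] = 2
        sc = _uniform_scalars((3, 3, 3))
        sc.md[0, 0, 0] = 1.0e-3
        sc.md[1, 0, 0] = 1.2e-3
        df = extract_indices(sc, _mpm_from_labels(labels), "s1", "healthy")
        left = df[df["side"] == "left"].iloc[0]
        assert left["md"] == pytest.approx(1.1e-3, rel=1e-12)

    def test_noiseless_phantom_tube_label_recovers_truth(
            self, curved_noiseless_subject, scheme):
        subj, manifest = curved_noiseless_subject
        maps = scalar_maps(eigendecompose(fit_tensor(subj.dwi, scheme)))
        labels = np.zeros(subj.dwi.shape[:3], np.uint8)
        labels[subj.truth_masks["left"]] = 1
        labels[subj.truth_masks["right"]] = 2
        df = extract_indices(maps, _mpm_from_labels(labels), "s1", "healthy")
        for side in ("left", "right"):
            row = df[df["side"] == side].iloc[0]
            assert row["ad"] == pytest.approx(subj.truth_params[side]["ad"],
                                              rel=1e-6)
            assert row["rd"] == pytest.approx(subj.truth_params[side]["rd"],
                                              rel=1e-6)

    def test_empty_label_warns_and_gives_nan(self):
        labels = np.zeros((3, 3, 3), np.uint8)
        labels[0, 0, 0] = 1  # right label empty
        with pytest.warns(UserWarning, match="empty"):
            df = extract_indices(_uniform_scalars((3, 3, 3)),
                                 _mpm_from_labels(labels), "s1", "healthy")
        assert df[df["side"] == "right"]["fa"].isna().all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            extract_indices(_uniform_scalars((3, 3, 3)),
                            _mpm_from_labels(np.zeros((4, 4, 4))), "s", "healthy")

    def test_patient_role_mapping(self):
        labels = np.zeros((3, 3, 3), np.uint8)
        labels[0, 0, 0] = 1
        labels[1, 0, 0] = 2
        df = extract_indices(_uniform_scalars((3, 3, 3)),
                             _mpm_from_labels(labels), "p1", "patient",
                             affected_side="right")
        assert df.loc[df["side"] == "right", "role"].item() == "affected"
        assert df.loc[df["side"] == "left", "role"].item() == "healthy_side"


class TestKS:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(0)
        passed = sum(ks_normality(rng.normal(10, 2, 1000)).p > 0.05
                     for _ in range(100))
        assert passed >= 95

    def test_skewed_samples_fail(self):
        rng = np.random.default_rng(1)
        assert ks_normality(rng.exponential(1.0, 1000)).p < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(10))
        with pytest.raises(ValueError, match="n >= 5"):
            ks_normality([1.0, 2.0])


class TestTTests:
    def test_paired_hand_computed_example(self):
        # differences (1,2,3,4,5): t = mean/ (sd/sqrt(5)) = 4.2426, df=4
        res = paired_ttest(np.array([2., 4, 6, 8, 10]), np.array([1., 2, 3, 4, 5]))
        assert res.t == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.0132, abs=2e-4)

    def test_identical_pairs_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_ttest(x, x)
        assert res.t == 0.0 and res.p == 1.0

    def test_paired_agrees_with_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = paired_ttest(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_unpaired_pooled_agrees_with_scipy_student(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=15), rng.normal(0.5, 1.0, size=25)
        res = unpaired_ttest(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == 38

    def test_length_mismatch_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="pooled variance"):
            unpaired_ttest([1.0, 1.0], [1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(-50, 50))
    def test_paired_invariant_to_common_shift(self, c):
        x = np.array([0.1, 0.5, -0.3, 0.8, 0.2])
        y = np.array([0.0, 0.2, 0.1, 0.4, -0.1])
        a = paired_ttest(x, y)
        b = paired_ttest(x + c, y + c)
        assert a.t == pytest.approx(b.t, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("df", [4, 17, 18, 53, 72])
    def test_p_from_t_matches_density_integration(self, df):
        # independent oracle: numerical integration of the t density
        def density(x):
            c = special.gamma((df + 1) / 2) / (
                np.sqrt(df * np.pi) * special.gamma(df / 2))
            return c * (1 + x**2 / df) ** (-(df + 1) / 2)

        for t in [0.0, 0.5, 1.0, 2.0, 3.5, 5.0]:
            tail, _ = integrate.quad(density, t, np.inf)
            assert p_from_t(t, df) == pytest.approx(2 * tail, abs=1e-6)


class TestTables:
    def test_pooled_table_sample_sizes_add_up(self):
        h = measurement_frame(
            phantom.draw_cohort_params(phantom.healthy_spec(18, rng_seed=1)), "all")
        p = measurement_frame(
            phantom.draw_cohort_params(phantom.patient_spec(19, rng_seed=2)), "all")
        t3 = build_table_pooled(pd.concat([h, p], ignore_index=True))
        n1_vs_n3 = t3[t3["comparison"] == "N1 vs N3"].iloc[0]
        n2_vs_n4 = t3[t3["comparison"] == "N2 vs N4"].iloc[0]
        assert (n1_vs_n3["n_patients"], n1_vs_n3["n_healthy"]) == (19, 36)
        assert (n2_vs_n4["n_patients"], n2_vs_n4["n_healthy"]) == (19, 55)
        assert n1_vs_n3["df"] == 53 and n2_vs_n4["df"] == 72

    def test_patient_table_shows_demyelination_signature(self):
        # strong-effect measurement-level cohort: FA down, RD up on affected side
        sig = 0
        for rep in range(5):
            mf = phantom.draw_cohort_params(
                phantom.patient_spec(19, rng_seed=100 + rep))
            t2 = build_table_patient(measurement_frame(mf, "patient"))
            fa = t2[t2["index"] == "FA"].iloc[0]
            rd = t2[t2["index"] == "RD"].iloc[0]
            # healthy_side minus affected: positive t for FA, negative for RD
            if fa["t"] > 0 and fa["p"] < 0.05 and rd["t"] < 0 and rd["p"] < 0.05:
                sig += 1
        assert sig >= 4

    def test_build_tables_requires_complete_columns(self):
        with pytest.raises(ValueError, match="columns"):
            build_tables(pd.DataFrame({"subject_id": [], "group": []}))

    def test_missing_cohort_rejected(self):
        p = measurement_frame(
            phantom.draw_cohort_params(phantom.patient_spec(19, rng_seed=3)), "all")
        with pytest.raises(ValueError):
            build_table_healthy(p)
        with pytest.raises(ValueError):
            build_table_pooled(p)

    def test_healthy_table_structure(self):
        h = measurement_frame(
            phantom.draw_cohort_params(phantom.healthy_spec(6, rng_seed=4)),
            "healthy")
        t1 = build_table_healthy(h)
        assert list(t1["index"]) == [i.upper() for i in INDEXES]
        assert set(t1.columns) >= {"left", "right", "p (t)", "p", "t", "df"}
        assert (t1["df"] == 5).all()
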