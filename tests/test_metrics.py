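"""Metric oracles: R^2, PCC(lnFC), grouped aggregation, DEG-restricted PCC."""

import numpy as np
import pytest

from perturbdiff.data import DEGSet
from perturbdiff.metrics import (
    STRATEGIES,
    deg_gene_pcc,
    evaluate_all,
    grouped_metric,
    ln_fc,
    pcc_lnfc,
    r_squared,
)

from conftest import make_dataset


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == pytest.approx(1.0, abs=1e-12)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_sums(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import r2_score

        rng = np.random.default_rng(5)
        y_true = rng.normal(size=60)
        y_pred = y_true + rng.normal(scale=0.4, size=60)
        assert r_squared(y_true, y_pred) == pytest.approx(r2_score(y_true, y_pred), abs=1e-12)

    def test_printed_formula_variant_centers_on_prediction_mean(self):
        y_true = np.array([1.0, 2.0, 3.0])
        y_pred = np.array([2.0, 3.0, 4.0])
        standard = r_squared(y_true, y_pred)
        printed = r_squared(y_true, y_pred, center="pred")
        expected = 1 - np.sum((y_true - y_pred) ** 2) / np.sum((y_true - y_pred.mean()) ** 2)
        assert printed == pytest.approx(expected, abs=1e-12)
        assert printed != standard

    def test_constant_truth_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(r_squared([2.0, 2.0], [1.0, 3.0]))


class TestLnFC:
    def test_no_change_is_zero(self):
        y = np.array([1.0, 2.0])
        assert np.allclose(ln_fc(y, y), 0.0)

    def test_uniform_shift(self):
        y = np.array([1.0, 2.0]) + 0.7
        assert np.allclose(ln_fc(y, [1.0, 2.0]), 0.7)

    def test_hand_subtraction(self):
        assert np.allclose(ln_fc([2.0, 3.0], [1.0, 1.0]), [1.0, 2.0])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ln_fc([1.0], [1.0, 2.0])


class TestPccLnfc:
    def test_identical_profiles_correlate_perfectly(self):
        y = np.array([1.0, 2.0, 4.0])
        x = np.zeros(3)
        assert pcc_lnfc(y, y, x) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flipped_fold_changes(self):
        x = np.zeros(3)
        y_true = np.array([1.0, -2.0, 3.0])
        assert pcc_lnfc(y_true, -y_true, x) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_pearson(self):
        from scipy.stats import pearsonr

        x = np.zeros(3)
        fc_true = np.array([1.0, 2.0, 3.0])
        fc_pred = np.array([1.0, 2.0, 2.0])
        expected = pearsonr(fc_true, fc_pred).statistic
        got = pcc_lnfc(fc_true, fc_pred, x)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_control_shift_invariance(self):
        rng = np.random.default_rng(1)
        y_true, y_pred = rng.normal(size=(2, 20))
        x = rng.normal(size=20)
        shift = rng.normal(size=20)
        a = pcc_lnfc(y_true, y_pred, x)
        b = pcc_lnfc(y_true + shift, y_pred + shift, x + shift)
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pcc_lnfc([1.0, 1.0], [1.0, 2.0], [0.0, 0.0]))


def _hand_grouped(dataset, preds, keys, metric):
    """Independent oracle: plain-loop group averaging + metric."""
    vals = []
    for key in sorted(set(keys)):
        idx = [i for i, k in enumerate(keys) if k == key]
        yt = dataset.perturbed[idx].mean(axis=0)
        yp = preds[idx].mean(axis=0)
        xc = dataset.control[idx].mean(axis=0)
        if metric == "R2":
            vals.append(1 - ((yt - yp) ** 2).sum() / ((yt - yt.mean()) ** 2).sum())
        else:
            vals.append(np.corrcoef(yt - xc, yp - xc)[0, 1])
    return float(np.mean(vals))


class TestGroupedMetric:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(8)
        n, g = 8, 3
        control = rng.normal(size=(n, g))
        perturbed = control + rng.normal(size=(n, g))
        smiles = ["CCO", "CCO", "CCO", "CCO", "CC", "CC", "CC", "CC"]
        dose = [1.0, 1.0, 10.0, 10.0, 1.0, 1.0, 10.0, 10.0]
        cells = ["A", "B", "A", "B", "A", "B", "A", "B"]
        ds = make_dataset(control, perturbed, smiles, dose, cells)
        preds = perturbed + rng.normal(scale=0.3, size=(n, g))
        return ds, preds

    def test_singleton_groups_equal_mean_of_per_sample_metrics(self):
        ds, preds = self._toy()
        per_record = [
            r_squared(ds.perturbed[i], preds[i]) for i in range(len(ds))
        ]
        assert grouped_metric(ds, preds, "per_sample", "R2") == pytest.approx(
            np.mean(per_record), abs=1e-12
        )

    def test_perfect_predictions_score_one_everywhere(self):
        ds, _ = self._toy()
        report = evaluate_all(ds, ds.perturbed.copy())
        for v in report.values.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("metric", ["R2", "PCC_lnFC"])
    @pytest.mark.parametrize("strategy", ["drug", "drug_dose", "cov_drug", "cov_drug_dose"])
    def test_matches_hand_loop_oracle(self, metric, strategy):
        ds, preds = self._toy()
        obs = ds.obs
        key_funcs = {
            "drug": lambda i: obs["drug_id"].iat[i],
            "drug_dose": lambda i: (obs["drug_id"].iat[i], obs["dose_um"].iat[i]),
            "cov_drug": lambda i: (obs["drug_id"].iat[i], obs["cell_line"].iat[i]),
            "cov_drug_dose": lambda i: (
                obs["drug_id"].iat[i],
                obs["cell_line"].iat[i],
                obs["dose_um"].iat[i],
            ),
        }
        keys = [key_funcs[strategy](i) for i in range(len(ds))]
        expected = _hand_grouped(ds, preds, keys, metric)
        assert grouped_metric(ds, preds, strategy, metric) == pytest.approx(expected, abs=1e-12)

    def test_report_has_ten_entries_and_order_invariance(self):
        ds, preds = self._toy()
        report = evaluate_all(ds, preds)
        assert len(report.values) == 10
        assert set(s for _, s in report.values) == set(STRATEGIES)
        perm = np.random.default_rng(0).permutation(len(ds))
        report2 = evaluate_all(ds.subset(perm), preds[perm])
        for k, v in report.values.items():
            assert report2.values[k] == pytest.approx(v, abs=1e-9)

    def test_noisier_predictions_score_lower(self):
        ds, _ = self._toy()
        rng = np.random.default_rng(123)
        base = ds.perturbed
        r2 = []
        for scale in (0.1, 1.0, 4.0):
            noisy = base + rng.normal(scale=scale, size=base.shape)
            r2.append(grouped_metric(ds, noisy, "per_sample", "R2"))
        assert r2[0] > r2[1] > r2[2]

    def test_gene_permutation_invariance(self):
        ds, preds = self._toy()
        perm = np.random.default_rng(4).permutation(ds.n_gene)
        ds2 = make_dataset(
            ds.control[:, perm],
            ds.perturbed[:, perm],
            list(ds.obs["smiles"]),
            list(ds.obs["dose_um"]),
            list(ds.obs["cell_line"]),
        )
        a = grouped_metric(ds, preds, "drug", "PCC_lnFC")
        b = grouped_metric(ds2, preds[:, perm], "drug", "PCC_lnFC")
        assert a == pytest.approx(b, abs=1e-12)

    def test_misaligned_predictions_raise(self):
        ds, preds = self._toy()
        with pytest.raises(ValueError):
            grouped_metric(ds, preds[:-1], "drug", "R2")

    def test_report_serialization(self, tmp_path):
        ds, preds = self._toy()
        report = evaluate_all(ds, preds)
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv", split="test")
        frame = report.to_frame("test")
        assert len(frame) == 10
        assert set(frame["metric"]) == {"R2", "PCC_lnFC"}


class TestDegGenePcc:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(9)
        n, g = 6, 4
        control = rng.normal(size=(n, g))
        perturbed = control + rng.normal(size=(n, g))
        ds = make_dataset(control, perturbed, ["CCO"] * n, [1.0] * n, ["A"] * n)
        return ds

    def test_perfect_predictions(self):
        ds = self._toy()
        degs = [DEGSet(drug_id="CCO", up_genes=["g0", "g1"], down_genes=["g2"])]
        out = deg_gene_pcc(ds, ds.perturbed.copy(), degs)
        assert out["CCO"] == pytest.approx(1.0, abs=1e-12)

    def test_sign_flipped_lnfc(self):
        ds = self._toy()
        degs = [DEGSet(drug_id="CCO", up_genes=["g0"], down_genes=[])]
        flipped = ds.control - (ds.perturbed - ds.control)
        assert deg_gene_pcc(ds, flipped, degs)["CCO"] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_pearson_single_gene(self):
        control = np.zeros((4, 2))
        perturbed = np.array([[1.0, 0], [2.0, 0], [3.0, 0], [4.0, 0]])
        preds = np.array([[1.0, 0], [2.0, 0], [2.0, 0], [5.0, 0]])
        ds = make_dataset(control, perturbed, ["CCO"] * 4, [1.0] * 4, ["A"] * 4)
        expected = np.corrcoef([1, 2, 3, 4], [1, 2, 2, 5])[0, 1]
        out = deg_gene_pcc(ds, preds, [DEGSet(drug_id="CCO", up_genes=["g0"], down_genes=[])])
        assert out["CCO"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_skipped_with_warning(self):
        control = np.zeros((4, 2))
        # gene g0 has constant lnFC across samples; g1 varies
        perturbed = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 1.0], [1.0, 4.0]])
        preds = perturbed + np.random.default_rng(0).normal(size=(4, 2))
        ds = make_dataset(control, perturbed, ["CCO"] * 4, [1.0] * 4, ["A"] * 4)
        degs = [DEGSet(drug_id="CCO", up_genes=["g0", "g1"], down_genes=[])]
        with pytest.warns(UserWarning, match="zero lnFC variance"):
            out = deg_gene_pcc(ds, preds, degs)
        assert "CCO" in out

    def test_unknown_gene_raises(self):
        ds = self._toy()
        with pytest.raises(ValueError, match="not in the dataset panel"):
            deg_gene_pcc(ds, ds.perturbed, [DEGSet(drug_id="CCO", up_genes=["zz"], down_genes=[])])
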