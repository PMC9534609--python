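"""Reading, imputation, studentized noise repair and normalisation."""

import numpy as np
import pytest

from heartsel.preprocess import (
    Normalizer,
    ParseError,
    PreprocessConfig,
    impute_missing,
    normalize,
    preprocess,
    read_cleveland,
    remove_noise_studentized,
)
from heartsel.synthetic import SynthConfig, generate_clinical, write_cleveland_csv

from conftest import make_table


class TestReadCleveland:
    def _write(self, tmp_path, lines):
        p = tmp_path / "data.csv"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_stage_binarisation(self, tmp_path):
        row = ",".join(["1.0"] * 13)
        path = self._write(tmp_path, [row + ",0", row + ",3"])
        table = read_cleveland(path)
        assert table.labels.tolist() == [0, 1]
        assert table.d == 13

    def test_question_mark_sets_mask(self, tmp_path):
        cells = ["1.0"] * 13
        cells[11] = "?"
        path = self._write(tmp_path, [",".join(cells) + ",1"])
        table = read_cleveland(path)
        assert table.missing_mask[0, 11]
        assert np.isnan(table.values[0, 11])
        assert not table.missing_mask[0, :11].any()

    def test_malformed_width_names_line(self, tmp_path):
        good = ",".join(["1.0"] * 13) + ",0"
        path = self._write(tmp_path, [good, "1.0,2.0,3"])
        with pytest.raises(ParseError, match=":2:"):
            read_cleveland(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        cells = ["1.0"] * 13
        cells[4] = "abc"
        path = self._write(tmp_path, [",".join(cells) + ",0"])
        with pytest.raises(ParseError, match="abc"):
            read_cleveland(path)

    def test_round_trip_with_generator(self, tmp_path):
        table, _ = generate_clinical(SynthConfig(n=40, d=13, missing_rate=0.05, seed=2))
        path = write_cleveland_csv(table, tmp_path / "synth.csv")
        back = read_cleveland(path)
        assert back.n == 40 and back.d == 13
        np.testing.assert_array_equal(back.missing_mask, table.missing_mask)
        np.testing.assert_array_equal(back.labels, table.labels)
        obs = ~table.missing_mask
        np.testing.assert_allclose(back.values[obs], table.values[obs])


class TestImpute:
    def test_median_fills_missing(self):
        mask = np.zeros((4, 1), dtype=bool)
        mask[2, 0] = True
        t = make_table([[1.0], [2.0], [np.nan], [4.0]], mask=mask)
        out = impute_missing(t)
        assert out.values[2, 0] == 2.0
        assert not out.missing_mask.any()

    def test_mean_strategy(self):
        mask = np.zeros((3, 1), dtype=bool)
        mask[0, 0] = True
        t = make_table([[np.nan], [1.0], [3.0]], mask=mask)
        out = impute_missing(t, PreprocessConfig(missing_strategy="mean"))
        assert out.values[0, 0] == 2.0

    def test_no_missing_is_identity(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]])
        assert impute_missing(t) is t

    def test_fully_missing_feature_errors(self):
        mask = np.ones((3, 1), dtype=bool)
        t = make_table([[np.nan]] * 3, mask=mask)
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(t)

    def test_observed_cells_bit_exact(self, small_table):
        table, _ = small_table
        out = impute_missing(table)
        obs = ~table.missing_mask
        np.testing.assert_array_equal(out.values[obs], table.values[obs])


def _external_studentized(y, X):
    """Brute-force externally studentized residuals via hat matrix."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    H = D @ np.linalg.pinv(D.T @ D) @ D.T
    resid = y - H @ y
    p = D.shape[1]
    h = np.diag(H)
    s2 = resid @ resid / (n - p)
    s2_i = (s2 * (n - p) - resid**2 / (1 - h)) / (n - p - 1)
    return resid / np.sqrt(s2_i * (1 - h))


class TestNoiseRepair:
    def test_quiet_table_unchanged(self, rng):
        t = make_table(rng.normal(size=(30, 3)))
        out, n_replaced = remove_noise_studentized(
            t, PreprocessConfig(studentized_threshold=1e6)
        )
        assert n_replaced == 0
        np.testing.assert_array_equal(out.values, t.values)

    def test_planted_outlier_is_the_unique_repair(self):
        values = np.random.default_rng(2).normal(size=(50, 4))
        values[7, 0] = 50.0  # gross outlier in an otherwise ~N(0,1) column
        # fixture validity: brute-force residuals flag exactly the planted cell
        flagged = []
        for j in range(4):
            r = _external_studentized(values[:, j], np.delete(values, j, axis=1))
            flagged += [(i, j) for i in np.flatnonzero(np.abs(r) > 3.0)]
        assert flagged == [(7, 0)]
        t = make_table(values)
        out, n_replaced = remove_noise_studentized(t)
        assert n_replaced == 1
        assert out.values[7, 0] == np.median(values[:, 0])
        untouched = np.ones(values.shape, dtype=bool)
        untouched[7, 0] = False
        np.testing.assert_array_equal(out.values[untouched], values[untouched])

    def test_matches_bruteforce_residuals(self, rng):
        values = rng.normal(size=(40, 3))
        values[3, 1] = 30.0
        values[20, 2] = -25.0
        expected = set()
        for j in range(3):
            r = _external_studentized(values[:, j], np.delete(values, j, axis=1))
            expected |= {(i, j) for i in np.flatnonzero(np.abs(r) > 3.0)}
        out, n_replaced = remove_noise_studentized(make_table(values))
        changed = {tuple(ij) for ij in np.argwhere(out.values != values)}
        assert changed == expected
        assert n_replaced == len(expected)

    def test_singular_design_falls_back(self, rng, caplog):
        base = rng.normal(size=(20, 2))
        values = np.column_stack([base, base[:, 0] * 2.0])  # exact collinearity
        with caplog.at_level("WARNING"):
            out, _ = remove_noise_studentized(make_table(values))
        assert "singular design" in caplog.text

    def test_requires_imputed_input(self):
        mask = np.zeros((3, 2), dtype=bool)
        mask[0, 0] = True
        t = make_table([[np.nan, 1.0], [1.0, 2.0], [2.0, 3.0]], mask=mask)
        with pytest.raises(ValueError, match="impute"):
            remove_noise_studentized(t)


class TestNormalize:
    def test_affine_map(self):
        out, _ = normalize(make_table([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        out, _ = normalize(make_table([[5.0], [5.0]]))
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0])

    def test_idempotent(self, rng):
        t = make_table(rng.random((20, 3)))
        once, _ = normalize(t)
        twice, _ = normalize(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_params_apply_to_held_out(self, rng):
        train = rng.normal(size=(30, 2))
        _, norm = normalize(make_table(train))
        held = norm.transform(train[:5] + 0.1)
        assert held.shape == (5, 2)
        assert (held >= 0).all() and (held <= 1).all()

    def test_zscore_option(self, rng):
        t = make_table(rng.normal(loc=3.0, size=(50, 2)))
        out, _ = normalize(t, PreprocessConfig(normalization="zscore"))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-12)


class TestPipeline:
    def test_full_pipeline_postconditions(self, small_table):
        table, _ = small_table
        out, params = preprocess(table)
        assert not out.missing_mask.any()
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        assert params["noise_cells_replaced"] >= 0
        assert len(params["normalization"]["loc"]) == table.d

    def test_label_blind(self, small_table):
        table, _ = small_table
        permuted = table.copy()
        permuted.labels = np.roll(permuted.labels, 3)
        a, _ = preprocess(table)
        b, _ = preprocess(permuted)
        np.testing.assert_array_equal(a.values, b.values)
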