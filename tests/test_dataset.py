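"""Spectral data model, CSV round-tripping and wavenumber trimming."""

import numpy as np
import pytest

from nirauth import (
    GeneratorConfig,
    SpectralDataset,
    make_grid,
    read_spectra_csv,
    simulate_dataset,
    trim_wavenumbers,
    write_spectra_csv,
)

from conftest import make_dataset


def _write_csv(path, header, rows):
    path.write_text("\n".join([",".join(header)] + [",".join(map(str, r)) for r in rows]))
    return path


class TestReadCsv:
    def test_basic_parse(self, tmp_path):
        p = _write_csv(
            tmp_path / "d.csv",
            ["sample_id", "label", "4000", "4010", "4020", "4030", "4040"],
            [["s1", "A", 1, 2, 3, 4, 5],
             ["s2", "A", 5, 4, 3, 2, 1],
             ["s3", "N", 2, 2, 2, 2, 3]],
        )
        ds = read_spectra_csv(p)
        assert (ds.n, ds.p) == (3, 5)
        assert list(ds.labels) == ["POS", "POS", "NEG"]
        assert ds.absorbance[0, 0] == 1.0

    def test_descending_wavenumbers_canonicalized(self, tmp_path):
        asc = _write_csv(
            tmp_path / "asc.csv",
            ["sample_id", "label", "4000", "4010", "4020"],
            [["s1", "POS", 1, 2, 3], ["s2", "NEG", 4, 5, 6], ["s3", "NEG", 7, 8, 9]],
        )
        desc = _write_csv(
            tmp_path / "desc.csv",
            ["sample_id", "label", "4020", "4010", "4000"],
            [["s1", "POS", 3, 2, 1], ["s2", "NEG", 6, 5, 4], ["s3", "NEG", 9, 8, 7]],
        )
        a, d = read_spectra_csv(asc), read_spectra_csv(desc)
        np.testing.assert_array_equal(a.wavenumbers, d.wavenumbers)
        np.testing.assert_array_equal(a.absorbance, d.absorbance)

    @pytest.mark.parametrize(
        "header,row,match",
        [
            (["sample_id", "label", "4000", "4010", "banana"], ["s1", "A", 1, 2, 3],
             "non-numeric"),
            (["sample_id", "label", "4000", "4010", "4020"], ["s1", "A", 1, "", 3],
             "missing value"),
        ],
    )
    def test_malformed_csv_rejected(self, tmp_path, header, row, match):
        rows = [[f"s{i}", *row[1:]] for i in range(3)]
        p = _write_csv(tmp_path / "bad.csv", header, rows)
        with pytest.raises(ValueError, match=match):
            read_spectra_csv(p)

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path / "dup.csv",
            ["sample_id", "label", "4000", "4010", "4020"],
            [["s1", "A", 1, 2, 3], ["s1", "N", 4, 5, 6]],
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra_csv(p)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        ds = make_dataset(n_pos=6, n_neg=4, p=50, seed=3)
        path = write_spectra_csv(ds, tmp_path / "rt.csv")
        back = read_spectra_csv(path)
        assert list(back.labels) == list(ds.labels)
        assert list(back.sample_ids) == list(ds.sample_ids)
        np.testing.assert_array_equal(back.wavenumbers, ds.wavenumbers)
        assert np.abs(back.absorbance - ds.absorbance).max() <= 1e-9

    def test_invalid_dataset_rejected_before_write(self, tmp_path):
        ds = make_dataset()
        ds.labels = np.array(["POS", "POS", "POS", "POS", "NEG", "NEG", ""], dtype=object)
        with pytest.raises(ValueError):
            write_spectra_csv(ds, tmp_path / "x.csv")


class TestTrim:
    def test_trim_matches_brute_force_count(self):
        config = GeneratorConfig(n_pos=3, n_neg=3, outlier_fraction=0.0)
        grid = make_grid(config)
        ds, _ = simulate_dataset(config)
        out = trim_wavenumbers(ds, 4000.0, 9000.0)
        expected = int(np.sum((grid >= 4000.0) & (grid <= 9000.0)))
        assert out.p == expected
        assert out.wavenumbers.max() <= 9000.0
        assert out.n == ds.n

    def test_full_range_is_identity(self, tiny_dataset):
        out = trim_wavenumbers(tiny_dataset, tiny_dataset.wavenumbers[0],
                               tiny_dataset.wavenumbers[-1])
        np.testing.assert_array_equal(out.absorbance, tiny_dataset.absorbance)

    def test_trim_is_idempotent(self, tiny_dataset):
        once = trim_wavenumbers(tiny_dataset, 4005, 4035)
        twice = trim_wavenumbers(once, 4005, 4035)
        np.testing.assert_array_equal(once.absorbance, twice.absorbance)
        np.testing.assert_array_equal(once.wavenumbers, twice.wavenumbers)

    def test_inverted_bounds_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="low < high"):
            trim_wavenumbers(tiny_dataset, 5000, 4000)

    def test_empty_interval_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="no wavenumbers"):
            trim_wavenumbers(tiny_dataset, 9000, 9100)


class TestInvariants:
    def test_nan_rejected_with_location(self):
        X = np.ones((3, 4))
        X[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            SpectralDataset(np.arange(4.0), X, np.array(["POS", "NEG", "NEG"]))

    def test_nonmonotone_axis_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpectralDataset(np.array([1.0, 3.0, 2.0]), np.ones((3, 3)),
                            np.array(["POS", "NEG", "NEG"]))
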