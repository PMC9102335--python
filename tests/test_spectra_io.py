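import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnsvm.errors import FormatError, LabelError, MetadataError, WindowError
from cnsvm.spectra_io import (
    HyperCube,
    SignatureSet,
    SpectralWindow,
    WavelengthGrid,
    crop_cube_to_window,
    crop_to_window,
    cube_to_signatures,
    read_cube,
    read_signature_table,
    signatures_to_image,
    write_cube,
    write_signature_table,
)
from cnsvm.synthetic_data import SimulationConfig, simulate_signatures


def small_set(n=3, channels=260):
    grid = WavelengthGrid(398.08, 2.2, channels)
    rng = np.random.default_rng(1)
    return SignatureSet(
        grid, rng.uniform(10, 60, size=(n, channels)), rng.integers(0, 2, size=n)
    )


class TestSignatureTables:
    def test_roundtrip_preserves_values_exactly(self, tmp_path):
        s = small_set()
        path = tmp_path / "table.csv"
        write_signature_table(s, path)
        back = read_signature_table(path)
        assert back.grid.n_channels == 260
        assert np.array_equal(back.reflectance, s.reflectance)
        assert np.array_equal(back.labels, s.labels)

    def test_three_row_table_with_sensor_headers(self, tmp_path):
        path = tmp_path / "t.csv"
        write_signature_table(small_set(n=3), path)
        s = read_signature_table(path)
        assert len(s) == 3 and s.grid.n_channels == 260
        assert s.grid.start_nm == pytest.approx(398.08)
        assert s.grid.spacing_nm == pytest.approx(2.2)

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_signature_table(small_set(n=4, channels=10), path, sep="\t")
        assert len(read_signature_table(path)) == 4

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_signature_table(path)

    def test_nonbinary_labels_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("500.00,502.20,label\n1.0,2.0,0\n3.0,4.0,1\n5.0,6.0,2\n")
        with pytest.raises(LabelError):
            read_signature_table(path)

    def test_missing_label_column_requires_flag(self, tmp_path):
        path = tmp_path / "unlabelled.csv"
        path.write_text("500.00,502.20\n1.0,2.0\n")
        with pytest.raises(LabelError):
            read_signature_table(path)
        s = read_signature_table(path, allow_unlabelled=True)
        assert not s.is_labelled and len(s) == 1

    def test_non_numeric_reflectance_names_row(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("500.00,502.20,label\n1.0,2.0,0\n1.0,oops,1\n")
        with pytest.raises(FormatError, match="row 1"):
            read_signature_table(path)

    def test_patient_column_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_bcc=5, n_healthy=5, seed=0)
        s = simulate_signatures(cfg)
        path = tmp_path / "p.csv"
        write_signature_table(s, path)
        back = read_signature_table(path)
        assert list(back.patient_ids) == list(s.patient_ids)


class TestWindowCropping:
    def test_study_window_keeps_94_channels(self):
        s = small_set(n=2)
        cropped = crop_to_window(s, SpectralWindow(573.45, 779.88))
        assert cropped.grid.n_channels == 94
        assert cropped.reflectance.shape == (2, 94)
        # closed interval on both ends
        assert cropped.grid.values[0] >= 573.45
        assert cropped.grid.values[-1] <= 779.88

    def test_full_window_is_identity(self):
        s = small_set(n=2)
        cropped = crop_to_window(s, SpectralWindow(300.0, 1100.0))
        assert cropped == s

    def test_empty_intersection_is_window_error(self):
        grid = WavelengthGrid(500.0, 2.2, 2)
        s = SignatureSet(grid, np.ones((1, 2)), np.array([0]))
        with pytest.raises(WindowError):
            crop_to_window(s, SpectralWindow(600.0, 700.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        start=st.floats(min_value=300, max_value=500),
        spacing=st.floats(min_value=0.5, max_value=5.0),
        channels=st.integers(min_value=1, max_value=120),
        lo=st.floats(min_value=250, max_value=900),
        width=st.floats(min_value=1.0, max_value=400),
    )
    def test_crop_is_idempotent_and_matches_brute_force(self, start, spacing, channels, lo, width):
        grid = WavelengthGrid(start, spacing, channels)
        s = SignatureSet(grid, np.ones((1, channels)))
        window = SpectralWindow(lo, lo + width)
        brute = sum(1 for w in grid.values if lo <= w <= lo + width)
        if brute == 0:
            with pytest.raises(WindowError):
                crop_to_window(s, window)
            return
        once = crop_to_window(s, window)
        assert once.grid.n_channels == brute
        twice = crop_to_window(once, window)
        assert twice == once


class TestCubes:
    def make_cube(self, rows=4, cols=5, channels=260):
        grid = WavelengthGrid(398.08, 2.2, channels)
        rng = np.random.default_rng(2)
        return HyperCube(grid, rng.uniform(0, 80, size=(rows, cols, channels)))

    def test_envi_roundtrip_is_bit_identical(self, tmp_path):
        cube = self.make_cube()
        path = str(tmp_path / "cube.raw")
        write_cube(cube, path)
        back = read_cube(path)
        assert back.shape == (4, 5, 260)
        assert np.array_equal(back.data, cube.data)
        assert np.allclose(back.grid.values, cube.grid.values, atol=1e-4)

    def test_npz_roundtrip(self, tmp_path):
        cube = self.make_cube(2, 3, 10)
        path = str(tmp_path / "cube.npz")
        write_cube(cube, path)
        back = read_cube(path)
        assert np.array_equal(back.data, cube.data)

    def test_missing_wavelengths_is_metadata_error(self, tmp_path):
        cube = self.make_cube(2, 2, 4)
        path = str(tmp_path / "c.raw")
        write_cube(cube, path)
        hdr = open(path + ".hdr").read()
        open(path + ".hdr", "w").write(
            "\n".join(l for l in hdr.splitlines() if not l.startswith("wavelength ="))
        )
        with pytest.raises(MetadataError):
            read_cube(path)

    def test_header_data_size_mismatch_is_format_error(self, tmp_path):
        cube = self.make_cube(2, 2, 4)
        path = str(tmp_path / "c.raw")
        write_cube(cube, path)
        data = open(path, "rb").read()
        open(path, "wb").write(data[:-16])
        with pytest.raises(FormatError):
            read_cube(path)

    def test_cube_to_signatures_row_major(self):
        cube = self.make_cube(2, 3, 94)
        s = cube_to_signatures(cube)
        assert len(s) == 6 and s.grid.n_channels == 94
        assert np.array_equal(s.reflectance[1 * 3 + 2], cube.data[1, 2])

    def test_single_pixel_cube(self):
        cube = self.make_cube(1, 1, 94)
        s = cube_to_signatures(cube)
        assert np.array_equal(s.reflectance[0], cube.data[0, 0])

    def test_reassembly_inverts_flattening(self):
        values = np.arange(6)
        img = signatures_to_image(values, (2, 3))
        assert img.shape == (2, 3) and img[1, 2] == 5

    def test_cube_cropping_matches_signature_cropping(self):
        cube = self.make_cube()
        w = SpectralWindow(573.45, 779.88)
        cropped = crop_cube_to_window(cube, w)
        assert cropped.shape == (4, 5, 94)
        assert np.array_equal(
            cube_to_signatures(cropped).reflectance,
            crop_to_window(cube_to_signatures(cube), w).reflectance,
        )
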