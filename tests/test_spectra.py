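"""Spectrum containers, JCAMP-DX reading, CSV round trips and regridding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chylopls import (
    JCAMPFormatError,
    SimulationConfig,
    Spectrum,
    SpectralDataset,
    assemble_dataset,
    lorentzian,
    read_dataset_csv,
    read_spectrum_jcamp,
    resample_to_grid,
    simulate_dataset,
    write_dataset_csv,
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def test_spectrum_requires_descending_finite_axis():
    with pytest.raises(ValueError, match="decreasing"):
        Spectrum(np.array([1.0, 2.0, 3.0]), np.zeros(3))
    with pytest.raises(ValueError, match="length"):
        Spectrum(np.array([3.0, 2.0]), np.zeros(3))
    with pytest.raises(ValueError, match="finite"):
        Spectrum(np.array([3.0, 2.0]), np.array([1.0, np.nan]))


def test_dataset_rejects_duplicate_ids_and_negative_y():
    ppm = np.array([2.0, 1.0])
    with pytest.raises(ValueError, match="duplicate"):
        SpectralDataset(ppm, np.zeros((2, 2)), ["a", "a"])
    with pytest.raises(ValueError, match="non-negative"):
        SpectralDataset(ppm, np.zeros((2, 2)), ["a", "b"], y=np.array([1.0, -0.1]))


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_jcamp_ascending_ppm_axis_is_reversed(tmp_path):
    """Five XYDATA points on an ascending ppm axis come back descending."""
    path = _write(tmp_path, "asc.jdx", """\
##TITLE= toy
##JCAMP-DX= 4.24
##DATA TYPE= NMR SPECTRUM
##XUNITS= PPM
##YUNITS= ARBITRARY
##FIRSTX= 1.0
##LASTX= 5.0
##NPOINTS= 5
##XYDATA= (X++(Y..Y))
1.0 10 20 30
4.0 40 50
##END=
""")
    sp = read_spectrum_jcamp(path)
    assert sp.sample_id == "asc"
    np.testing.assert_allclose(sp.ppm, [5.0, 4.0, 3.0, 2.0, 1.0])
    np.testing.assert_allclose(sp.intensity, [50, 40, 30, 20, 10])


def test_jcamp_hz_axis_divided_by_observe_frequency(tmp_path):
    """A Hz axis is converted via ppm = Hz / 500.13; three points hand-checked."""
    path = _write(tmp_path, "hz.jdx", """\
##TITLE= hz axis
##XUNITS= HZ
##.OBSERVE FREQUENCY= 500.13
##FIRSTX= 500.13
##LASTX= 1500.39
##NPOINTS= 3
##XYDATA= (X++(Y..Y))
500.13 1 2 3
##END=
""")
    sp = read_spectrum_jcamp(path)
    # hand conversion: 500.13/500.13 = 1, 1000.26/500.13 = 2, 1500.39/500.13 = 3
    np.testing.assert_allclose(sp.ppm, [3.0, 2.0, 1.0], atol=1e-12)
    np.testing.assert_allclose(sp.intensity, [3, 2, 1])


def test_jcamp_yfactor_is_applied(tmp_path):
    path = _write(tmp_path, "yf.jdx", """\
##TITLE= scaled
##XUNITS= PPM
##YFACTOR= 0.5
##FIRSTX= 0.0
##LASTX= 1.0
##NPOINTS= 2
##XYDATA= (X++(Y..Y))
0.0 4 8
##END=
""")
    np.testing.assert_allclose(read_spectrum_jcamp(path).intensity, [4.0, 2.0])


@pytest.mark.parametrize(
    "mutation, message",
    [
        ("##NPOINTS= 5", "##NPOINTS= 0"),  # degenerate point count
        ("##XUNITS= PPM", ""),  # missing axis units
        ("##FIRSTX= 1.0", ""),  # missing axis start
    ],
)
def test_jcamp_degenerate_headers_raise_format_error(tmp_path, mutation, message):
    base = """\
##TITLE= bad
##XUNITS= PPM
##FIRSTX= 1.0
##LASTX= 5.0
##NPOINTS= 5
##XYDATA= (X++(Y..Y))
1.0 10 20 30
4.0 40 50
##END=
"""
    path = _write(tmp_path, "bad.jdx", base.replace(mutation, message))
    with pytest.raises(JCAMPFormatError):
        read_spectrum_jcamp(path)


def test_jcamp_compressed_tables_are_rejected_with_record_name(tmp_path):
    path = _write(tmp_path, "sqz.jdx", """\
##TITLE= squeezed
##XUNITS= PPM
##FIRSTX= 1.0
##LASTX= 3.0
##NPOINTS= 3
##XYDATA= (X++(Y..Y))
1.0A0B0C0
##END=
""")
    with pytest.raises(JCAMPFormatError, match="XYDATA"):
        read_spectrum_jcamp(path)


def test_jcamp_ntuples_single_page(tmp_path):
    path = _write(tmp_path, "nt.jdx", """\
##TITLE= ntuples toy
##DATA TYPE= NMR SPECTRUM
##NTUPLES= NMR SPECTRUM
##VAR_NAME=  FREQUENCY, SPECTRUM/REAL
##SYMBOL=    X, R
##UNITS=     PPM, ARBITRARY
##VAR_DIM=   4, 4
##FIRST=     4.0, 0
##LAST=      1.0, 0
##FACTOR=    1.0, 2.0
##PAGE= N=1
##DATA TABLE= (X++(R..R)), XYDATA
4.0 1 2
2.0 3 4
##END NTUPLES= NMR SPECTRUM
##END=
""")
    sp = read_spectrum_jcamp(path)
    np.testing.assert_allclose(sp.ppm, [4.0, 3.0, 2.0, 1.0])
    np.testing.assert_allclose(sp.intensity, [2.0, 4.0, 6.0, 8.0])


# ---------------------------------------------------------------------------
# CSV exchange format
# ---------------------------------------------------------------------------

def _toy_dataset(with_y=True):
    ppm = np.array([2.0, 1.5, 1.0, 0.5])
    X = np.arange(12, dtype=float).reshape(3, 4)
    y = np.array([0.2, 0.5, 1.1]) if with_y else None
    return SpectralDataset(ppm, X, ["s1", "s2", "s3"], y=y)


def test_csv_round_trip_reproduces_dataset(tmp_path):
    ds = _toy_dataset()
    path = tmp_path / "toy.csv"
    write_dataset_csv(ds, path)
    back = read_dataset_csv(path)
    np.testing.assert_allclose(back.ppm, ds.ppm, rtol=1e-9)
    np.testing.assert_allclose(back.X, ds.X, rtol=1e-9)
    np.testing.assert_allclose(back.y, ds.y, rtol=1e-9)
    assert back.sample_ids == ds.sample_ids


def test_csv_ascending_header_is_stored_descending(tmp_path):
    path = tmp_path / "asc.csv"
    path.write_text("sample_id,0.5,1.0,1.5\na,1,2,3\nb,4,5,6\n")
    ds = read_dataset_csv(path)
    np.testing.assert_allclose(ds.ppm, [1.5, 1.0, 0.5])
    np.testing.assert_allclose(ds.X, [[3, 2, 1], [6, 5, 4]])


def test_csv_missing_cell_is_named(tmp_path):
    path = tmp_path / "gap.csv"
    path.write_text("sample_id,2.0,1.0\na,1,2\nb,,4\n")
    with pytest.raises(ValueError, match="'b'"):
        read_dataset_csv(path)


def test_csv_duplicate_ids_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text("sample_id,2.0,1.0\na,1,2\na,3,4\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_dataset_csv(path)


# ---------------------------------------------------------------------------
# regridding
# ---------------------------------------------------------------------------

def test_resample_identity_on_own_grid():
    sp = Spectrum(np.linspace(5, 0, 11), np.arange(11, dtype=float))
    out = resample_to_grid(sp, sp.ppm)
    np.testing.assert_array_equal(out.intensity, sp.intensity)


def test_resample_exact_on_linear_spectrum():
    """intensity = 2·ppm resampled at midpoints is exactly linear."""
    ppm = np.linspace(4.0, 0.0, 9)
    sp = Spectrum(ppm, 2.0 * ppm)
    mid = (ppm[:-1] + ppm[1:]) / 2
    out = resample_to_grid(sp, mid)
    np.testing.assert_allclose(out.intensity, 2.0 * mid, atol=1e-14)


def test_resample_lorentzian_close_to_analytic():
    """Downsampling a finely sampled Lorentzian stays within 1e-4 of the
    analytic lineshape (relative to peak height)."""
    fine = np.arange(2000, 500, -1) / 1000.0  # descending 2.0 -> 0.5 at 0.001 ppm
    sp = Spectrum(fine, lorentzian(fine, 1.28, 0.03, 1.0))
    coarse = fine[::2]
    out = resample_to_grid(sp, coarse)
    analytic = lorentzian(coarse, 1.28, 0.03, 1.0)
    assert np.abs(out.intensity - analytic).max() < 1e-4


def test_resample_refuses_extrapolation():
    sp = Spectrum(np.linspace(5, 1, 5), np.zeros(5))
    with pytest.raises(ValueError, match="beyond"):
        resample_to_grid(sp, np.linspace(6, 2, 5))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_resample_idempotent_on_own_output_grid(seed):
    r = np.random.default_rng(seed)
    ppm = np.sort(r.uniform(0, 6, size=30))[::-1]
    ppm += np.arange(30)[::-1] * 1e-9  # guarantee strict monotonicity
    sp = Spectrum(ppm, r.standard_normal(30))
    grid = np.linspace(ppm[0] - 1e-6, ppm[-1] + 1e-6, 17)[::-1].copy()
    grid = np.sort(grid)[::-1]
    once = resample_to_grid(sp, grid)
    twice = resample_to_grid(once, grid)
    np.testing.assert_allclose(twice.intensity, once.intensity, rtol=0, atol=1e-12)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_assemble_identical_spectra_gives_identical_rows():
    ppm = np.linspace(5, 0, 21)
    a = Spectrum(ppm, np.sin(ppm), "a")
    b = Spectrum(ppm, np.sin(ppm), "b")
    ds = assemble_dataset([a, b], ppm)
    np.testing.assert_array_equal(ds.X[0], ds.X[1])


def test_assemble_partial_references_error():
    ppm = np.linspace(5, 0, 21)
    spectra = [Spectrum(ppm, np.zeros(21) + i, f"s{i}") for i in range(2)]
    with pytest.raises(ValueError, match="missing"):
        assemble_dataset(spectra, ppm, references={"s0": 1.0})


def test_assemble_round_trips_simulator_ground_truth():
    """Disassembling a simulated dataset into spectra and reassembling on the
    same grid reproduces X and the ground-truth y."""
    cfg = SimulationConfig(seed=99, grid_points=401, grid_lo=0.5, grid_hi=2.5)
    ds = simulate_dataset(12, cfg)
    spectra = [ds.spectrum(i) for i in range(ds.n_samples)]
    refs = {sid: float(v) for sid, v in zip(ds.sample_ids, ds.y)}
    back = assemble_dataset(spectra, ds.ppm, references=refs)
    np.testing.assert_allclose(back.X, ds.X, rtol=1e-12)
    np.testing.assert_allclose(back.y, ds.y, rtol=1e-12)
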