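import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytogeom.spectra import (
    Spectrum,
    SpectrumError,
    difference,
    difference_extrema,
    lambda_max,
    normalize,
    read_spectrum,
    write_spectrum,
)
from phytogeom.synthetic import BandSpec, make_synthetic_spectrum


def gaussian_spectrum(center, width=20.0, amplitude=1.0, grid=(240.0, 800.0, 1.0)):
    return make_synthetic_spectrum(BandSpec(bands=((center, width, amplitude),), grid=grid))


# ---------------------------------------------------------------------------
# I/O


def test_read_sorts_rows(tmp_path):
    p = tmp_path / "s.csv"
    p.write_text("700,0.5\n650,0.2\n750,0.1\n")
    s = read_spectrum(p)
    assert len(s) == 3
    np.testing.assert_array_equal(s.wavelengths, [650, 700, 750])
    np.testing.assert_allclose(s.absorbance, [0.2, 0.5, 0.1])


def test_shuffled_rows_equal_sorted(tmp_path):
    rows = [(640 + i, 0.01 * i) for i in range(20)]
    a = tmp_path / "a.csv"
    a.write_text("\n".join(f"{w},{v}" for w, v in rows))
    b = tmp_path / "b.csv"
    shuffled = rows[::2] + rows[1::2]
    b.write_text("\n".join(f"{w}\t{v}" for w, v in shuffled))
    sa, sb = read_spectrum(a), read_spectrum(b)
    np.testing.assert_array_equal(sa.wavelengths, sb.wavelengths)
    np.testing.assert_allclose(sa.absorbance, sb.absorbance)


def test_duplicate_wavelengths_averaged(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("700,0.5\n700,0.7\n710,0.1\n720,0.2\n")
    s = read_spectrum(p)
    assert s.absorbance[list(s.wavelengths).index(700)] == pytest.approx(0.6)


def test_parse_error_reports_line_number(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("650,0.1\n700,oops\n750,0.3\n")
    with pytest.raises(SpectrumError, match=":2:"):
        read_spectrum(p)


def test_too_few_points_rejected(tmp_path):
    p = tmp_path / "tiny.csv"
    p.write_text("650,0.1\n700,0.2\n")
    with pytest.raises(SpectrumError, match=">= 3"):
        read_spectrum(p)


def test_write_read_round_trip(tmp_path):
    s = gaussian_spectrum(700.0)
    back = read_spectrum(write_spectrum(s, tmp_path / "rt.csv"))
    np.testing.assert_allclose(back.wavelengths, s.wavelengths)
    np.testing.assert_allclose(back.absorbance, s.absorbance, atol=1e-8)


# ---------------------------------------------------------------------------
# normalize


def test_normalize_unit_maximum():
    s = gaussian_spectrum(700.0, amplitude=2.0)
    n = normalize(s)
    mask = (n.wavelengths >= 550) & (n.wavelengths <= 800)
    assert n.absorbance[mask].max() == pytest.approx(1.0)


def test_normalize_idempotent():
    s = gaussian_spectrum(700.0, amplitude=3.7)
    once = normalize(s)
    twice = normalize(once)
    assert np.max(np.abs(twice.absorbance - once.absorbance)) < 1e-12


@settings(derandomize=True, max_examples=25, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_normalize_scale_invariant(scale):
    s = gaussian_spectrum(700.0)
    scaled = Spectrum(s.wavelengths, s.absorbance * scale, s.label)
    np.testing.assert_allclose(
        normalize(scaled).absorbance, normalize(s).absorbance, atol=1e-12
    )


def test_normalize_rejects_nonpositive_maximum():
    flat = Spectrum(np.array([600.0, 700.0, 800.0]), np.zeros(3))
    with pytest.raises(SpectrumError, match="normalize"):
        normalize(flat)


# ---------------------------------------------------------------------------
# difference


def test_difference_of_identical_spectra_is_zero():
    s = gaussian_spectrum(700.0)
    d = difference(s, s)
    assert np.max(np.abs(d.absorbance)) == 0.0


def test_difference_antisymmetric_on_shared_grid():
    a = gaussian_spectrum(700.0)
    b = gaussian_spectrum(750.0)
    np.testing.assert_allclose(
        difference(a, b).absorbance, -difference(b, a).absorbance, atol=1e-15
    )


def test_difference_extrema_locate_band_centers():
    a = gaussian_spectrum(700.0)
    b = gaussian_spectrum(750.0)
    (pos_wl, pos_v), (neg_wl, neg_v) = difference_extrema(difference(a, b))
    assert abs(pos_wl - 700.0) <= 2.0 and pos_v > 0
    assert abs(neg_wl - 750.0) <= 2.0 and neg_v < 0


def test_difference_interpolates_offset_grids():
    a = gaussian_spectrum(700.0, grid=(600.0, 800.0, 1.0))
    b = gaussian_spectrum(700.0, grid=(600.5, 800.5, 1.0))
    d = difference(a, b)
    # bound: max |f''| * h^2 / 8 for linear interpolation, h = 1 nm
    width = 20.0
    bound = (1.0 / width**2) * 1.0**2 / 8.0
    assert np.max(np.abs(d.absorbance)) < bound


def test_empty_overlap_rejected():
    a = gaussian_spectrum(300.0, grid=(240.0, 400.0, 1.0))
    b = gaussian_spectrum(700.0, grid=(600.0, 800.0, 1.0))
    with pytest.raises(SpectrumError, match="overlap"):
        difference(a, b)


# ---------------------------------------------------------------------------
# lambda max


@pytest.mark.parametrize(
    "center,step",
    [(706.0, 1.0), (698.0, 1.0), (702.0, 1.0), (701.5, 0.5)],
)
def test_lambda_max_exact_on_synthetic_bands(center, step):
    s = gaussian_spectrum(center, grid=(240.0, 800.0, step))
    assert lambda_max(s).lambda_max == center


def test_lambda_max_invariances():
    s = gaussian_spectrum(706.0)
    base = lambda_max(s).lambda_max
    scaled = Spectrum(s.wavelengths, 7.3 * s.absorbance)
    lifted = Spectrum(s.wavelengths, s.absorbance + 0.5)
    assert lambda_max(scaled).lambda_max == base
    assert lambda_max(lifted).lambda_max == base


def test_monotone_window_flags_endpoint():
    wl = np.arange(600.0, 800.0)
    s = Spectrum(wl, np.linspace(0.0, 1.0, len(wl)))
    summary = lambda_max(s, window=(650.0, 780.0))
    assert summary.lambda_max == 780.0
    assert "monotone-in-window" in summary.flags


def test_window_outside_grid_rejected():
    s = gaussian_spectrum(700.0, grid=(600.0, 800.0, 1.0))
    with pytest.raises(SpectrumError, match="window"):
        lambda_max(s, window=(100.0, 200.0))


# ---------------------------------------------------------------------------
# Pr -> Pfr sign pattern


@pytest.mark.parametrize("shift", [0.06, 0.1, 0.3, 0.5])
def test_pr_to_pfr_difference_sign_pattern(shift):
    """Converting Pr (~700 nm) to Pfr (~750 nm) gives a negative lobe near
    700 and a positive lobe near 750 for any mixture change above 5%."""
    f_dark = 0.9  # Pr fraction dark-adapted
    f_illum = f_dark - shift
    def mixture(f):
        return make_synthetic_spectrum(
            BandSpec(bands=((700.0, 20.0, f), (750.0, 20.0, 1.0 - f)))
        )
    d = difference(mixture(f_illum), mixture(f_dark))
    near = lambda wl, x: np.abs(d.wavelengths - x) <= 5
    assert d.absorbance[near(d.wavelengths, 700.0)].mean() < 0
    assert d.absorbance[near(d.wavelengths, 750.0)].mean() > 0
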