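"""UV-vis absorption-spectrum processing.

Phytochrome photoconversion is followed spectroscopically: a dark-adapted
spectrum and an illuminated spectrum are normalized, subtracted
(illuminated minus dark) and the absorption maxima extracted. A Pr -> Pfr
conversion shows up as a negative difference lobe near the Pr band
(~700 nm) and a positive lobe near the Pfr band (~750 nm).

Spectra are two-column (wavelength nm, absorbance AU) series on the
240-800 nm range used for the measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "Spectrum",
    "SpectralSummary",
    "SpectrumError",
    "read_spectrum",
    "write_spectrum",
    "normalize",
    "difference",
    "lambda_max",
    "difference_extrema",
]

#: default normalization window: the red/far-red Q band region
NORM_WINDOW = (550.0, 800.0)
#: default search window for the absorption maximum
PEAK_WINDOW = (650.0, 780.0)


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """Wavelength/absorbance series on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise SpectrumError("wavelengths and absorbance must be 1-D and equal length")
        if len(wl) < 3:
            raise SpectrumError(f"spectrum has {len(wl)} points; need >= 3")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(ab))):
            raise SpectrumError("non-finite values in spectrum")
        self.wavelengths = wl
        self.absorbance = ab

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class SpectralSummary:
    lambda_max: float  # nm
    max_absorbance: float
    window: tuple[float, float]
    diff_positive: tuple[float, float] | None = None  # (nm, value)
    diff_negative: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.lambda_max <= hi):
            raise SpectrumError("lambda_max outside its search window")


def read_spectrum(path: str | Path, label: str = "") -> Spectrum:
    """Read a two-column (wavelength, absorbance) text file.

    Comma-, tab- or whitespace-delimited; rows may be unordered; duplicate
    wavelengths are averaged. Non-numeric rows raise with their line number.
    """
    path = Path(path)
    wl: list[float] = []
    ab: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            try:
                w, a = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                raise SpectrumError(f"{path}:{lineno}: cannot parse spectrum row {s!r}") from None
            wl.append(w)
            ab.append(a)
    if len(wl) < 3:
        raise SpectrumError(f"{path}: only {len(wl)} data points; need >= 3")
    arr_wl = np.array(wl)
    arr_ab = np.array(ab)
    uniq, inverse = np.unique(arr_wl, return_inverse=True)
    mean_ab = np.zeros_like(uniq)
    counts = np.bincount(inverse)
    np.add.at(mean_ab, inverse, arr_ab)
    mean_ab /= counts
    return Spectrum(uniq, mean_ab, label or path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {spectrum.label}\n")
        for w, a in zip(spectrum.wavelengths, spectrum.absorbance):
            fh.write(f"{w:.4f},{a:.8f}\n")
    return path


def _window_mask(spectrum: Spectrum, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not mask.any():
        raise SpectrumError(f"window {window} does not overlap the {spectrum.wavelengths[0]:.0f}-"
                            f"{spectrum.wavelengths[-1]:.0f} nm grid")
    return mask


def normalize(spectrum: Spectrum, window: tuple[float, float] = NORM_WINDOW) -> Spectrum:
    """Scale so the maximum within ``window`` is 1 (idempotent)."""
    mask = _window_mask(spectrum, window)
    peak = float(spectrum.absorbance[mask].max())
    if peak <= 0:
        raise SpectrumError(f"cannot normalize: maximum in {window} nm window is {peak}")
    return Spectrum(spectrum.wavelengths.copy(), spectrum.absorbance / peak, spectrum.label)


def difference(a: Spectrum, b: Spectrum) -> Spectrum:
    """a minus b on a's grid restricted to the overlap (b linearly interpolated)."""
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo >= hi:
        raise SpectrumError("spectra do not overlap in wavelength")
    mask = (a.wavelengths >= lo) & (a.wavelengths <= hi)
    if mask.sum() < 3:
        raise SpectrumError("overlap contains fewer than 3 grid points")
    wl = a.wavelengths[mask]
    b_interp = np.interp(wl, b.wavelengths, b.absorbance)
    label = f"{a.label} - {b.label}" if (a.label or b.label) else "difference"
    return Spectrum(wl, a.absorbance[mask] - b_interp, label)


def lambda_max(
    spectrum: Spectrum,
    window: tuple[float, float] = PEAK_WINDOW,
) -> SpectralSummary:
    """Absorption maximum within a window, after 5-point median smoothing.

    The result has the grid's resolution (no interpolation; sub-nm maxima come
    from sub-nm grids). Ties in the smoothed signal are broken by the raw
    absorbance, so a symmetric on-grid band is recovered exactly. A maximum
    sitting on the window edge is flagged ``monotone-in-window``.
    """
    mask = _window_mask(spectrum, window)
    smooth = median_filter(spectrum.absorbance, size=5, mode="nearest")
    idx = np.flatnonzero(mask)
    sm = smooth[idx]
    top = sm.max()
    ties = idx[sm >= top - 1e-15 * max(abs(top), 1.0)]
    best = ties[int(np.argmax(spectrum.absorbance[ties]))]
    flags = []
    if best == idx[0] or best == idx[-1]:
        flags.append("monotone-in-window")
    return SpectralSummary(
        lambda_max=float(spectrum.wavelengths[best]),
        max_absorbance=float(spectrum.absorbance[best]),
        window=window,
        flags=flags,
    )


def difference_extrema(diff: Spectrum) -> tuple[tuple[float, float], tuple[float, float]]:
    """(wavelength, value) of the most positive and most negative difference."""
    i_pos = int(np.argmax(diff.absorbance))
    i_neg = int(np.argmin(diff.absorbance))
    return (
        (float(diff.wavelengths[i_pos]), float(diff.absorbance[i_pos])),
        (float(diff.wavelengths[i_neg]), float(diff.absorbance[i_neg])),
    )
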