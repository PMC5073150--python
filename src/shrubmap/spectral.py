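"""Sensor band model, field-spectrum resampling, and spectral angle mapping.

The imaging spectrometer is modelled as 72 contiguous channels starting at
363 nm with a constant 9.6 nm width (363-1051 nm). Field spectrometer
spectra are resampled to these channels by averaging the source samples
that fall in each channel. Spectral angle mapper (SAM) rule images record,
per pixel, the angle between the pixel's spectral vector and a target
species' reference spectra; smaller angles mean closer matches, and the
statistic is invariant to positive scaling (illumination magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid

__all__ = [
    "BandSet",
    "Spectrum",
    "SpectralLibrary",
    "CHANNEL_SUBSETS",
    "band_for_wavelength",
    "resample_spectrum",
    "spectral_angle",
    "sam_rule_image",
]


@dataclass(frozen=True)
class BandSet:
    """Contiguous, non-overlapping, constant-width sensor channels.

    Channel ``i`` (1-based) spans the half-open interval
    ``[start + (i-1)*width, start + i*width)`` nm.
    """

    n_bands: int = 72
    start_nm: float = 363.0
    width_nm: float = 9.6

    def __post_init__(self) -> None:
        if self.n_bands < 1 or self.width_nm <= 0:
            raise ValueError("invalid band set")

    @property
    def end_nm(self) -> float:
        return self.start_nm + self.n_bands * self.width_nm

    @property
    def centers(self) -> np.ndarray:
        return self.start_nm + (np.arange(self.n_bands) + 0.5) * self.width_nm

    @property
    def edges(self) -> np.ndarray:
        return self.start_nm + np.arange(self.n_bands + 1) * self.width_nm


@dataclass
class Spectrum:
    """A single wavelength -> reflectance(%) sampling."""

    wavelength_nm: np.ndarray
    reflectance_pct: np.ndarray
    species: str = ""
    sample_id: str = ""
    provenance: str = "field"  # field | image

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.wavelength_nm.size != self.reflectance_pct.size:
            raise ValueError("wavelength and reflectance lengths differ")
        if self.wavelength_nm.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class SpectralLibrary:
    """Named collections of reference spectra (>=1 per species/class)."""

    spectra: dict[str, list[Spectrum]] = field(default_factory=dict)

    def add(self, spectrum: Spectrum) -> None:
        self.spectra.setdefault(spectrum.species, []).append(spectrum)

    def species(self) -> list[str]:
        return sorted(self.spectra)

    def __getitem__(self, species: str) -> list[Spectrum]:
        return self.spectra[species]

    def __contains__(self, species: str) -> bool:
        return species in self.spectra

    def resampled(self, species: str, bands: BandSet) -> np.ndarray:
        """(n_spectra, n_bands) matrix of the species' resampled spectra."""
        return np.vstack([resample_spectrum(s, bands) for s in self.spectra[species]])


#: Key discriminating channels (1-based) per species, fixed configuration.
CHANNEL_SUBSETS: dict[str, tuple[int, ...]] = {
    "blackberry": (16, 21, 31, 37, 41, 59, 63, 65, 68, 70),
    "ivy": (22, 24, 26, 35, 40, 52, 58, 64),
}


def band_for_wavelength(lambda_nm: float, bands: BandSet = BandSet()) -> int:
    """1-based index of the half-open channel containing ``lambda_nm``."""
    if not (bands.start_nm <= lambda_nm < bands.end_nm):
        raise ValueError(
            f"wavelength {lambda_nm} nm outside sensor range "
            f"[{bands.start_nm}, {bands.end_nm}) nm"
        )
    return int((lambda_nm - bands.start_nm) // bands.width_nm) + 1


def resample_spectrum(spectrum: Spectrum, bands: BandSet = BandSet()) -> np.ndarray:
    """Average source samples into each sensor channel.

    Channel value = unweighted mean of source samples whose wavelengths fall
    in the channel's half-open interval. A channel containing no source
    sample takes the value of the nearest source sample to its center.
    """
    wl = spectrum.wavelength_nm
    if wl[0] > bands.start_nm or wl[-1] < bands.end_nm - bands.width_nm:
        # tolerate partial coverage of the outermost bands only
        if wl[0] > bands.centers[0] or wl[-1] < bands.centers[-1]:
            raise ValueError("spectrum does not cover the sensor band range")
    idx = np.floor((wl - bands.start_nm) / bands.width_nm).astype(np.int64)
    inside = (idx >= 0) & (idx < bands.n_bands)
    sums = np.bincount(idx[inside], weights=spectrum.reflectance_pct[inside],
                       minlength=bands.n_bands)
    counts = np.bincount(idx[inside], minlength=bands.n_bands)
    out = np.full(bands.n_bands, np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    if not np.all(has):  # nearest-sample fallback for empty channels
        empty = np.flatnonzero(~has)
        nearest = np.searchsorted(wl, bands.centers[empty])
        nearest = np.clip(nearest, 1, wl.size - 1)
        left_closer = (bands.centers[empty] - wl[nearest - 1]) <= (wl[nearest] - bands.centers[empty])
        pick = np.where(left_closer, nearest - 1, nearest)
        out[empty] = spectrum.reflectance_pct[pick]
    return out


def spectral_angle(target: np.ndarray, reference: np.ndarray) -> float:
    """SAM angle arccos(<t,r>/(|t||r|)) in radians, clipped into [0, pi].

    Returns ``nan`` for a zero-length (all-zero) vector.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    if t.shape != r.shape:
        raise ValueError("vectors must have equal length")
    nt = np.linalg.norm(t)
    nr = np.linalg.norm(r)
    if nt == 0 or nr == 0:
        return float("nan")
    c = np.clip(np.dot(t, r) / (nt * nr), -1.0, 1.0)
    return float(np.arccos(c))


def _angles_to_references(pixels: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """(n_pixels, n_refs) SAM angles; rows with zero norm -> nan."""
    pn = np.linalg.norm(pixels, axis=1, keepdims=True)
    rn = np.linalg.norm(refs, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (pixels @ refs.T) / (pn * rn.T)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang[(pn[:, 0] == 0), :] = np.nan
    return ang


def sam_rule_image(
    cube: np.ndarray,
    references: list[Spectrum] | np.ndarray,
    bands: BandSet,
    grid: RasterGrid,
    channel_subset: tuple[int, ...] | None = None,
    open_mask: np.ndarray | None = None,
    aggregation: str = "min",
) -> RasterGrid:
    """Per-pixel SAM angle raster against a species' reference spectra.

    Parameters
    ----------
    cube:
        Reflectance cube ``(n_bands, nrow, ncol)`` in percent.
    references:
        The species' training spectra (resampled on the fly if given as
        :class:`Spectrum` objects) or a pre-resampled ``(n_refs, n_bands)``
        array.
    channel_subset:
        Optional 1-based channel indices; ``None`` uses all channels.
    open_mask:
        Boolean raster on ``grid``; pixels where it is False (e.g. >=20%
        canopy cover above 2.5 m) are nodata in the rule image.
    aggregation:
        ``"min"`` (per-pixel minimum angle across reference spectra,
        multi-endmember rule behaviour) or ``"mean"`` (angle to the mean
        reference spectrum).
    """
    if cube.shape[0] != bands.n_bands:
        raise ValueError("cube band count does not match band set")
    if cube.shape[1:] != grid.shape:
        raise ValueError("cube spatial shape does not match grid")
    if isinstance(references, np.ndarray):
        refs = np.atleast_2d(np.asarray(references, dtype=float))
    else:
        refs = np.vstack([resample_spectrum(s, bands) for s in references])
    if refs.shape[1] != bands.n_bands:
        raise ValueError("reference length does not match band set")

    if channel_subset is not None:
        sub = np.asarray(channel_subset, dtype=int) - 1
        if np.any(sub < 0) or np.any(sub >= bands.n_bands):
            raise ValueError("channel subset outside the cube's channels")
    else:
        sub = np.arange(bands.n_bands)

    pix = cube[sub].reshape(sub.size, -1).T.astype(float)
    refsub = refs[:, sub]
    if aggregation == "mean":
        refsub = refsub.mean(axis=0, keepdims=True)
    elif aggregation != "min":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    ang = _angles_to_references(pix, refsub)
    rule = np.min(ang, axis=1) if ang.shape[1] > 1 else ang[:, 0]
    rule = rule.reshape(grid.shape)
    if open_mask is not None:
        rule = np.where(np.asarray(open_mask, bool), rule, np.nan)
    return grid.like(rule, nodata=np.nan)
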