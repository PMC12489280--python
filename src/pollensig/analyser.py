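"""The pollen-analyser software path and its camera forward model.

The field device flashes the load with six LEDs (365, 390, 395, 460, 530,
625 nm) and photographs it each time with an RGB camera whose IR filter has
been removed, so the red channel keeps useful sensitivity into the near
infrared. Per load the software (1) segments the red channel of the red-LED
image to find the region of interest, then (2) averages the three camera
channels inside the ROI for each of the six images, giving 18 features named
``{excitation}{channel}`` (e.g. ``365r``).

The forward model used by the simulator mirrors this: the expected camera
value is a gain times the 1 nm Riemann sum of the emission spectrum against
the channel sensitivity curve, plus (for the visible LEDs only) a direct
reflectance term, plus a dark baseline, clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .channels import PIXEL_CHANNELS, RGB_EXCITATIONS, EXCITATION_WAVELENGTHS
from .datamodel import (
    ANALYSER_FEATURE_NAMES,
    AnalyserFeatures,
    AnalyserImageSet,
    EmissionSpectrum,
)
from .errors import NoLoadDetected, UsageError

#: Components smaller than this many pixels are not considered a load.
MIN_LOAD_PIXELS = 50

#: Minimum Otsu class separation (grey levels) for a threshold to be meaningful;
#: below this the 625 nm red plane is treated as contrast-free (no load).
MIN_CLASS_CONTRAST = 8.0

_CHANNEL_INDEX = {"r": 0, "g": 1, "b": 2}


@dataclass
class RoiMask:
    """Binary region-of-interest mask over one image plane."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise UsageError("ROI mask must be a 2-D boolean raster")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid of the mask."""
        rows, cols = np.nonzero(self.mask)
        return float(rows.mean()), float(cols.mean())


@dataclass
class CameraResponse:
    """Per-channel spectral sensitivity of the camera, 1 nm over 400-900 nm.

    The default emulates an IMX219-class sensor without its IR-cut filter:
    Gaussian channel curves (blue 460/σ50, green 530/σ50, red 600/σ60) with a
    flat near-infrared floor of 0.2 on every channel above 700 nm.
    """

    wavelengths: np.ndarray
    curves: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        for ch in PIXEL_CHANNELS:
            if ch not in self.curves:
                raise UsageError(f"camera response missing channel {ch!r}")
            c = np.asarray(self.curves[ch], dtype=np.float64)
            if c.shape != self.wavelengths.shape:
                raise UsageError("camera curves must be sampled on the wavelength grid")
            if (c < 0).any() or c.sum() <= 0:
                raise UsageError("camera curves must be non-negative with positive area")
            self.curves[ch] = c

    @classmethod
    def default(cls, nir_floor: float = 0.2) -> "CameraResponse":
        wl = np.arange(400.0, 901.0)
        centers = {"b": (460.0, 50.0), "g": (530.0, 50.0), "r": (600.0, 60.0)}
        curves = {}
        for ch, (mu, sigma) in centers.items():
            c = np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
            c = np.where(wl > 700.0, np.maximum(c, nir_floor), c)
            curves[ch] = np.clip(c, 0.0, 1.0)
        return cls(wavelengths=wl, curves=curves)

    def at(self, channel: str, wavelengths: np.ndarray) -> np.ndarray:
        """Sensitivity of one channel at the given wavelengths (1 nm lookup)."""
        idx = np.rint(np.asarray(wavelengths, dtype=np.float64) - self.wavelengths[0]).astype(int)
        if idx.min() < 0 or idx.max() >= self.wavelengths.size:
            raise UsageError("wavelength outside the 400-900 nm camera grid")
        return self.curves[channel][idx]


@dataclass
class OpticalScene:
    """Inputs to the forward model for one load.

    ``albedo_rgb`` is the load's diffuse reflectance per camera channel;
    ``spectra`` its emission spectrum per excitation; ``led_intensity`` the
    source strength per excitation (camera units); ``baseline`` the dark level
    per channel; ``gain`` converts summed spectral flux to camera units.
    """

    albedo_rgb: np.ndarray
    spectra: dict[int, EmissionSpectrum]
    led_intensity: dict[int, float]
    baseline: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: float = 0.006

    def __post_init__(self) -> None:
        self.albedo_rgb = np.asarray(self.albedo_rgb, dtype=np.float64)
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        if self.albedo_rgb.shape != (3,) or (self.albedo_rgb < 0).any() or (
            self.albedo_rgb > 1
        ).any():
            raise UsageError("albedo_rgb must be three reflectances in [0, 1]")
        if self.baseline.shape != (3,) or (self.baseline < 0).any() or (
            self.baseline > 255
        ).any():
            raise UsageError("baseline must be three dark levels in [0, 255]")


def segment_load(image_set: AnalyserImageSet) -> RoiMask:
    """Locate the pollen load in the red channel of the 625 nm (red-LED) image.

    Otsu's threshold splits the plane in two; the class whose mean red
    intensity differs most from the image-border mean (the white paper disc)
    is taken as foreground. The largest connected component is kept, holes
    filled, and the contour eroded by one pixel to guard against background
    bleed. Raises :class:`NoLoadDetected` when no component of at least
    ``MIN_LOAD_PIXELS`` pixels survives.
    """
    if 625 not in image_set.images:
        raise UsageError("segmentation requires the 625 nm image")
    red = image_set.images[625][:, :, 0]
    if float(red.max() - red.min()) < 1e-9:
        raise NoLoadDetected("625 nm red channel has no contrast")
    thr = threshold_otsu(red)
    high = red > thr
    if not high.any() or high.all():
        raise NoLoadDetected("Otsu threshold produced a single class")
    border = np.concatenate([red[0, :], red[-1, :], red[1:-1, 0], red[1:-1, -1]])
    border_mean = float(border.mean())
    mean_high = float(red[high].mean())
    mean_low = float(red[~high].mean())
    if abs(mean_high - mean_low) < MIN_CLASS_CONTRAST:
        raise NoLoadDetected(
            f"Otsu classes differ by {abs(mean_high - mean_low):.2f} grey levels "
            f"(< {MIN_CLASS_CONTRAST}); image is contrast-free"
        )
    fg = high if abs(mean_high - border_mean) > abs(mean_low - border_mean) else ~high

    labels = cc_label(fg, connectivity=2)
    if labels.max() == 0:
        raise NoLoadDetected("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    if sizes[biggest] < MIN_LOAD_PIXELS:
        raise NoLoadDetected(
            f"largest component has {sizes[biggest]} px (< {MIN_LOAD_PIXELS})"
        )
    comp = labels == biggest
    comp = ndimage.binary_fill_holes(comp)
    comp = ndimage.binary_erosion(comp)  # 1 px, 4-connected cross
    if not comp.any():
        raise NoLoadDetected("component vanished after erosion")
    return RoiMask(mask=comp)


def extract_features(image_set: AnalyserImageSet, mask: RoiMask) -> AnalyserFeatures:
    """Average each camera channel inside the ROI for all six images.

    Returns the 18 features in canonical 365r..625b order; feature
    ``{exc}{c}`` is the arithmetic mean of channel ``c`` over the mask pixels
    of the ``exc``-illumination image.
    """
    if mask.mask.shape != image_set.shape:
        raise UsageError(
            f"mask shape {mask.mask.shape} does not match images {image_set.shape}"
        )
    if mask.area == 0:
        raise UsageError("cannot extract features from an empty ROI")
    values = []
    for exc in EXCITATION_WAVELENGTHS:
        img = image_set.images[exc]
        for ch in PIXEL_CHANNELS:
            values.append(float(img[:, :, _CHANNEL_INDEX[ch]][mask.mask].mean()))
    return AnalyserFeatures(np.array(values))


def camera_forward(scene: OpticalScene, camera: CameraResponse) -> AnalyserFeatures:
    """Noise-free expected 18 features for a scene.

    For every excitation and channel c::

        value_c = clip(gain * sum_λ S_exc(λ) * R_c(λ) + baseline_c, 0, 255)

    with an additional direct-reflectance term
    ``led_intensity * albedo_c * R_c(λ_led)`` for the visible-LED excitations
    (460, 530, 625 nm), whose light the camera sees directly; the UV LEDs are
    outside the sensitivity curves, so those images are fluorescence-only.
    The response is linear in the spectral intensities before clipping.
    """
    values = []
    for exc in EXCITATION_WAVELENGTHS:
        if exc not in scene.spectra:
            raise UsageError(f"scene is missing the {exc} nm emission spectrum")
        spec = scene.spectra[exc]
        wl = spec.wavelengths
        for i, ch in enumerate(PIXEL_CHANNELS):
            v = scene.gain * float(np.sum(spec.intensities * camera.at(ch, wl)))
            if exc in RGB_EXCITATIONS:
                led = scene.led_intensity.get(exc, 0.0)
                v += led * float(scene.albedo_rgb[i]) * float(camera.at(ch, np.array([exc]))[0])
            v += float(scene.baseline[i])
            values.append(float(np.clip(v, 0.0, 255.0)))
    return AnalyserFeatures(np.array(values))
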