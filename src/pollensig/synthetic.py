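"""Synthetic fluorophore-mixture species models and dataset generation.

Each species is modelled as a small mixture of Gaussian emission bands
("fluorophores"), each with its own excitation efficiency per LED. The
generator reproduces the qualitative structure of real pollen-load campaigns:

* species-stable peak positions with strong load-to-load intensity
  variability (a global log-normal brightness factor per load plus a
  Dirichlet perturbation of the mixture weights);
* a prominent blue emission band (peak inside 415-512 nm under 365 nm
  excitation) for every species, plus frequent far-red bands whose
  grid-edge shoulder is what the 740 nm-truncated signature sees;
* colour tones (white..dark) that set the load's reflectance in the imaging
  path, with dark loads carrying a larger analyser noise multiplier;
* a pair of "congeneric" species sharing fluorophores and differing only in
  mixture weights.

Randomness is counter-based: one global seed fans out through
``numpy.random.SeedSequence([seed, stream, species_index, ...])`` substreams,
so adding a species never perturbs the loads of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .analyser import CameraResponse, OpticalScene, camera_forward
from .channels import EXCITATION_WAVELENGTHS
from .datamodel import (
    AnalyserFeatures,
    AnalyserImageSet,
    AnalyserRecord,
    Dataset,
    EmissionSpectrum,
    PollenLoadSpectra,
)
from .errors import GenerationError, UsageError
from .signature import emission_grid

#: Diffuse reflectance (r, g, b) per colour tone.
TONE_ALBEDO = {
    "white": (0.55, 0.60, 0.62),
    "yellow": (0.55, 0.50, 0.15),
    "orange": (0.52, 0.30, 0.12),
    "green": (0.28, 0.48, 0.22),
    "dark": (0.10, 0.08, 0.08),
}

_TONE_CYCLE = ("white", "yellow", "orange", "green", "dark")


@dataclass(frozen=True)
class Fluorophore:
    """One Gaussian emission band with per-excitation efficiency."""

    emission_center_nm: float
    emission_sigma_nm: float
    excitation_profile: tuple[float, ...]  # efficiency in [0,1] per L1..L6

    def __post_init__(self) -> None:
        if not 400.0 <= self.emission_center_nm <= 850.0:
            raise UsageError("fluorophore emission centre must lie in 400-850 nm")
        if not 8.0 <= self.emission_sigma_nm <= 45.0:
            raise UsageError("fluorophore emission sigma must lie in 8-45 nm")
        if len(self.excitation_profile) != 6 or max(self.excitation_profile) <= 0:
            raise UsageError("excitation profile needs six efficiencies, one > 0")


@dataclass
class Variability:
    """Load-to-load variability knobs.

    ``intensity_lognorm_sigma`` — sigma of the global log-normal brightness
    factor (unitless); ``weight_dirichlet_conc`` — Dirichlet concentration of
    the mixture-weight jitter (0 disables it); ``additive_noise_sd`` —
    per-sample Gaussian noise in intensity units.
    """

    intensity_lognorm_sigma: float = 0.35
    weight_dirichlet_conc: float = 60.0
    additive_noise_sd: float = 4.0


@dataclass
class SpeciesSpectralModel:
    """Generative ground truth for one species."""

    species: str
    fluorophores: tuple[Fluorophore, ...]
    weights: np.ndarray
    tone: str
    amplitude: float
    variability: Variability = field(default_factory=Variability)
    analyser_noise_multiplier: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.fluorophores) < 2 or len(self.fluorophores) > 6:
            raise UsageError("a species model uses 2-6 fluorophores")
        if self.weights.shape != (len(self.fluorophores),) or (self.weights <= 0).any():
            raise UsageError("weights must be positive, one per fluorophore")
        self.weights = self.weights / self.weights.sum()
        if self.tone not in TONE_ALBEDO:
            raise UsageError(f"unknown tone {self.tone!r}")
        if self.tone == "dark" and self.analyser_noise_multiplier <= 1.0:
            self.analyser_noise_multiplier = 3.0

    @property
    def albedo_rgb(self) -> np.ndarray:
        return np.array(TONE_ALBEDO[self.tone])

    def mean_intensities(self, excitation_nm: int, weights: Optional[np.ndarray] = None) -> np.ndarray:
        """Noise-free emission trace on the excitation's grid."""
        w = self.weights if weights is None else np.asarray(weights, dtype=np.float64)
        wl = emission_grid(excitation_nm)
        k = EXCITATION_WAVELENGTHS.index(excitation_nm)
        out = np.zeros(wl.size)
        for fw, fl in zip(w, self.fluorophores):
            eff = fl.excitation_profile[k]
            if eff <= 0:
                continue
            out += (
                self.amplitude
                * fw
                * eff
                * np.exp(-0.5 * ((wl - fl.emission_center_nm) / fl.emission_sigma_nm) ** 2)
            )
        return out

    def mean_spectrum(self, excitation_nm: int) -> EmissionSpectrum:
        return EmissionSpectrum(excitation_nm, self.mean_intensities(excitation_nm))

    def mean_signature(self) -> np.ndarray:
        """Noise-free 1381-vector (L1..L6 concatenation)."""
        return np.concatenate(
            [self.mean_intensities(exc) for exc in EXCITATION_WAVELENGTHS]
        )


@dataclass
class DiscGeometry:
    """Placement of the rendered pollen-load disc on the white paper field."""

    height: int = 96
    width: int = 96
    center: tuple[float, float] = (48.0, 48.0)
    radius: float = 28.0

    def validate(self) -> None:
        cy, cx = self.center
        if (
            cy - self.radius < 0
            or cx - self.radius < 0
            or cy + self.radius >= self.height
            or cx + self.radius >= self.width
        ):
            raise UsageError("disc extends outside the image bounds")


@dataclass
class SimConfig:
    """Study-scale configuration of the synthetic campaign.

    Defaults emulate the real campaign's scale: 14 species with about two
    dozen loads each, of which a few spectroscopy measurements are lost
    (24 x 14 = 336 analyser rows, 333 spectroscopy rows with the default
    ``n_dropped=3``).
    """

    seed: int
    n_species: int = 14
    loads_per_species: int = 24
    n_dropped: int = 3
    image_height: int = 96
    image_width: int = 96
    disc_radius: float = 28.0
    pixel_noise_sd: float = 2.0
    feature_noise_sd: float = 1.5
    min_separation: float = 200.0
    led_intensity: float = 230.0
    baseline: float = 2.0
    gain: float = 0.006
    variability: Variability = field(default_factory=Variability)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise UsageError("SimConfig requires an explicit seed")
        if min(self.n_species, self.loads_per_species) < 1 or self.n_dropped < 0:
            raise UsageError("counts must be >= 1 (n_dropped >= 0)")


def _rng(*key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(list(key))))


def _draw_model(species: str, tone: str, rng: np.random.Generator,
                variability: Variability) -> SpeciesSpectralModel:
    def jitter(base: tuple[float, ...]) -> tuple[float, ...]:
        return tuple(float(np.clip(b + rng.normal(0, 0.08), 0.0, 1.0)) for b in base)

    fluors = [
        # blue band (terpenoid-like): strong under UV, peaks in 415-512 nm
        Fluorophore(
            emission_center_nm=float(rng.uniform(425, 495)),
            emission_sigma_nm=float(rng.uniform(12, 28)),
            excitation_profile=jitter((1.0, 0.9, 0.85, 0.25, 0.05, 0.0)),
        ),
        # green/yellow band (flavonoid-like)
        Fluorophore(
            emission_center_nm=float(rng.uniform(545, 655)),
            emission_sigma_nm=float(rng.uniform(18, 40)),
            excitation_profile=jitter((0.5, 0.6, 0.65, 0.9, 0.7, 0.05)),
        ),
    ]
    if rng.random() < 0.7:
        # far-red band (chlorophyll-like); the 740 nm grid edge sees its shoulder
        fluors.append(
            Fluorophore(
                emission_center_nm=float(rng.uniform(690, 820)),
                emission_sigma_nm=float(rng.uniform(15, 35)),
                excitation_profile=jitter((0.4, 0.4, 0.45, 0.7, 0.5, 0.4)),
            )
        )
    if rng.random() < 0.5:
        centers = [f.emission_center_nm for f in fluors]
        for _ in range(50):
            c = float(rng.uniform(560, 700))
            if min(abs(c - x) for x in centers) >= 40.0:
                fluors.append(
                    Fluorophore(
                        emission_center_nm=c,
                        emission_sigma_nm=float(rng.uniform(10, 40)),
                        excitation_profile=tuple(rng.uniform(0.05, 0.9, size=5))
                        + (float(rng.uniform(0.05, 0.3)),),
                    )
                )
                break
    weights = rng.uniform(0.5, 1.5, size=len(fluors))
    weights[0] *= 1.6  # keep the blue band prominent
    return SpeciesSpectralModel(
        species=species,
        fluorophores=tuple(fluors),
        weights=weights,
        tone=tone,
        amplitude=float(rng.uniform(800, 2500)),
        variability=variability,
    )


def make_species_models(config: SimConfig) -> list[SpeciesSpectralModel]:
    """Generate ``config.n_species`` pairwise-distinguishable species models.

    Deterministic given ``config.seed``. Species 2 is "congeneric" with
    species 1 (same fluorophores, amplitude and tone; different mixture
    weights). Models are regenerated (fresh substream) until every pairwise
    L2 distance between noise-free mean signatures exceeds
    ``config.min_separation``; more than 100 attempts for one species raises
    :class:`GenerationError`.
    """
    models: list[SpeciesSpectralModel] = []
    signatures: list[np.ndarray] = []
    for i in range(config.n_species):
        species = f"species_{i + 1:02d}"
        tone = _TONE_CYCLE[i % len(_TONE_CYCLE)]
        for attempt in range(100):
            rng = _rng(config.seed, 0, i, attempt)
            if i == 1 and config.n_species >= 2:
                base = models[0]
                w = rng.uniform(0.5, 1.5, size=len(base.fluorophores))
                w = w[::-1].copy()
                w[-1] *= 1.6  # invert the emphasis relative to the sibling
                cand = SpeciesSpectralModel(
                    species=species,
                    fluorophores=base.fluorophores,
                    weights=w,
                    tone=base.tone,
                    amplitude=base.amplitude,
                    variability=config.variability,
                )
            else:
                cand = _draw_model(species, tone, rng, config.variability)
            sig = cand.mean_signature()
            if all(
                float(np.linalg.norm(sig - s)) > config.min_separation for s in signatures
            ):
                models.append(cand)
                signatures.append(sig)
                break
        else:
            raise GenerationError(
                f"could not place species {species} at min separation "
                f"{config.min_separation} within 100 attempts"
            )
    return models


def sample_load_spectra(
    model: SpeciesSpectralModel, n: int, seed: int
) -> list[PollenLoadSpectra]:
    """Sample ``n`` loads from a species model.

    Per load: a global LogNormal(0, sigma) brightness factor multiplies a
    Dirichlet-perturbed mixture evaluated on every excitation grid, plus
    additive Gaussian noise, clipped at zero. Peak positions are fixed by the
    model, so they are constant across loads of a species.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    var = model.variability
    records = []
    for l in range(n):
        rng = _rng(seed, l)
        scale = float(np.exp(rng.normal(0.0, var.intensity_lognorm_sigma))) if var.intensity_lognorm_sigma > 0 else 1.0
        if var.weight_dirichlet_conc > 0 and np.isfinite(var.weight_dirichlet_conc):
            w = rng.dirichlet(var.weight_dirichlet_conc * model.weights)
        else:
            w = model.weights
        spectra: dict[int, EmissionSpectrum] = {}
        for exc in EXCITATION_WAVELENGTHS:
            clean = scale * model.mean_intensities(exc, weights=w)
            if var.additive_noise_sd > 0:
                clean = clean + rng.normal(0.0, var.additive_noise_sd, size=clean.size)
            spectra[exc] = EmissionSpectrum(exc, np.clip(clean, 0.0, None))
        records.append(
            PollenLoadSpectra(
                load_id=f"{model.species}-{l + 1:03d}",
                species=model.species,
                spectra=spectra,
                tone=model.tone,
            )
        )
    return records


def scene_for_load(
    model: SpeciesSpectralModel,
    record: PollenLoadSpectra,
    config: Optional[SimConfig] = None,
) -> OpticalScene:
    """Forward-model scene for one sampled load."""
    led = config.led_intensity if config is not None else 230.0
    base = config.baseline if config is not None else 2.0
    gain = config.gain if config is not None else 0.006
    return OpticalScene(
        albedo_rgb=model.albedo_rgb,
        spectra=record.spectra,
        led_intensity={exc: led for exc in (460, 530, 625)},
        baseline=np.full(3, base),
        gain=gain,
    )


def render_image_set(
    model: SpeciesSpectralModel,
    camera: Optional[CameraResponse] = None,
    geometry: Optional[DiscGeometry] = None,
    seed: int = 0,
    pixel_noise_sd: float = 2.0,
    config: Optional[SimConfig] = None,
    background_only: bool = False,
) -> AnalyserImageSet:
    """Render the six LED images of one sampled load on its white paper disc.

    Background pixels show the paper: a direct-reflectance value under the
    visible LEDs and near-dark under UV. In-disc pixels carry the
    noise-free :func:`camera_forward` expectation plus per-pixel Gaussian
    noise whose sd is ``pixel_noise_sd`` times the model's dark-tone
    multiplier. With ``pixel_noise_sd=0`` the in-disc values equal the
    forward expectation exactly. The returned set's ``geometry`` records the
    true centre/radius and the expected features.
    """
    camera = camera or CameraResponse.default()
    geometry = geometry or DiscGeometry()
    geometry.validate()
    record = sample_load_spectra(model, 1, seed)[0]
    scene = scene_for_load(model, record, config)
    expected = camera_forward(scene, camera)

    led = scene.led_intensity
    base = scene.baseline
    yy, xx = np.mgrid[0 : geometry.height, 0 : geometry.width]
    cy, cx = geometry.center
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= geometry.radius**2

    rng = _rng(seed, 10_000)
    mult = model.analyser_noise_multiplier
    images: dict[int, np.ndarray] = {}
    idx = 0
    for exc in EXCITATION_WAVELENGTHS:
        img = np.empty((geometry.height, geometry.width, 3))
        for c, ch in enumerate(("r", "g", "b")):
            if exc in (460, 530, 625):
                bg = base[c] + led[exc] * 1.0 * float(camera.at(ch, np.array([exc]))[0])
            else:
                bg = base[c] + (6.0 if ch == "b" else 1.0)  # faint paper glow under UV
            plane = np.full((geometry.height, geometry.width), bg)
            if not background_only:
                plane[disc] = expected.values[idx]
            if pixel_noise_sd > 0:
                noise = rng.normal(0.0, pixel_noise_sd, size=plane.shape)
                noise[disc] *= mult
                plane = plane + noise
            img[:, :, c] = plane
            idx += 1
        images[exc] = np.clip(img, 0.0, 255.0)
    return AnalyserImageSet(
        images=images,
        geometry={
            "center": (cy, cx),
            "radius": geometry.radius,
            "expected_features": expected.values.tolist(),
            "species": model.species,
            "load_id": record.load_id,
        },
    )


@dataclass
class SimResult:
    """Output of :func:`make_dataset`."""

    spectroscopy: Dataset
    analyser: Dataset
    truth: pd.DataFrame
    models: list[SpeciesSpectralModel]


def make_dataset(config: SimConfig, camera: Optional[CameraResponse] = None) -> SimResult:
    """Generate a full labelled campaign for both modalities.

    Every load is measured twice from the same sampled spectra: the
    spectroscopy table stores the spectra themselves, the analyser table the
    camera-forward features plus feature-level Gaussian noise (sd scaled by
    the dark-tone multiplier). ``n_dropped`` loads are then removed at random
    from the spectroscopy table only, emulating the small shortfall between
    the two campaigns.
    """
    camera = camera or CameraResponse.default()
    models = make_species_models(config)
    spectro_records: list[PollenLoadSpectra] = []
    analyser_records: list[AnalyserRecord] = []
    for i, model in enumerate(models):
        load_seed = int(_rng(config.seed, 1, i).integers(0, 2**31 - 1))
        loads = sample_load_spectra(model, config.loads_per_species, seed=load_seed)
        noise_rng = _rng(config.seed, 2, i)
        for rec in loads:
            spectro_records.append(rec)
            expected = camera_forward(scene_for_load(model, rec, config), camera)
            noisy = expected.values + noise_rng.normal(
                0.0,
                config.feature_noise_sd * model.analyser_noise_multiplier,
                size=18,
            )
            analyser_records.append(
                AnalyserRecord(
                    load_id=rec.load_id,
                    species=rec.species,
                    features=AnalyserFeatures(np.clip(noisy, 0.0, 255.0)),
                    tone=model.tone,
                )
            )
    truth = pd.DataFrame(
        {
            "load_id": [r.load_id for r in spectro_records],
            "species": [r.species for r in spectro_records],
            "tone": [r.tone for r in spectro_records],
        }
    )
    if config.n_dropped > 0:
        drop_rng = _rng(config.seed, 3)
        drop_idx = set(
            drop_rng.choice(len(spectro_records), size=config.n_dropped, replace=False).tolist()
        )
        spectro_records = [r for j, r in enumerate(spectro_records) if j not in drop_idx]
    return SimResult(
        spectroscopy=Dataset(spectro_records, "spectroscopy", provenance="synthetic"),
        analyser=Dataset(analyser_records, "analyser", provenance="synthetic"),
        truth=truth,
        models=models,
    )
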