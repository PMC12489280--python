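"""Core domain types.

The unit object is the corbicular pollen load. Two measurement modalities
describe it:

* spectroscopy — six emission spectra per load, one per excitation wavelength,
  on 1 nm grids that start 50 nm above the excitation and end at 740 nm;
  concatenated they form a 1381-feature spectral signature;
* analyser — six RGB images per load (one per LED), reduced to 18 channel-mean
  features named ``{excitation}{channel}`` (e.g. ``365r``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .channels import EXCITATION_WAVELENGTHS, PIXEL_CHANNELS, label_for
from .errors import UsageError, ValidationError

#: Emission grids stop at this wavelength for every excitation.
EMISSION_END_NM = 740
#: Emission grids start this many nm above the excitation wavelength.
EMISSION_OFFSET_NM = 50

#: Recognised pollen-load colour tones (descriptive metadata, never a feature).
TONES = ("white", "yellow", "orange", "green", "dark")

#: Canonical order of the 18 analyser feature names: excitation ascending, r/g/b.
ANALYSER_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{exc}{ch}" for exc in EXCITATION_WAVELENGTHS for ch in PIXEL_CHANNELS
)

_ANALYSER_NAME_RE = re.compile(r"^(\d{3})([rgb])$")
_SPECTRO_NAME_RE = re.compile(r"^L([1-6])_(\d{3})$")


def emission_start_nm(excitation_nm: int) -> int:
    """First emission wavelength recorded for an excitation."""
    return int(excitation_nm) + EMISSION_OFFSET_NM


def grid_length(excitation_nm: int) -> int:
    """Number of 1 nm emission samples for an excitation (= 691 - excitation)."""
    return EMISSION_END_NM - emission_start_nm(excitation_nm) + 1


@dataclass
class EmissionSpectrum:
    """One excitation's emission trace on its fixed 1 nm grid.

    ``intensities[i]`` is the fluorescence (arbitrary units) at emission
    wavelength ``excitation_nm + 50 + i``; the grid ends at 740 nm.
    """

    excitation_nm: int
    intensities: np.ndarray
    bandwidth_nm: float = 10.0  # instrument metadata only

    def __post_init__(self) -> None:
        if self.excitation_nm not in EXCITATION_WAVELENGTHS:
            raise UsageError(
                f"unsupported excitation {self.excitation_nm} nm; "
                f"supported: {EXCITATION_WAVELENGTHS}"
            )
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        expected = grid_length(self.excitation_nm)
        if self.intensities.ndim != 1 or self.intensities.size != expected:
            raise ValidationError(
                f"excitation {self.excitation_nm} nm expects {expected} emission "
                f"samples ({emission_start_nm(self.excitation_nm)}-{EMISSION_END_NM} nm), "
                f"got shape {self.intensities.shape}"
            )

    @property
    def emission_start_nm(self) -> int:
        return emission_start_nm(self.excitation_nm)

    @property
    def emission_end_nm(self) -> int:
        return EMISSION_END_NM

    @property
    def wavelengths(self) -> np.ndarray:
        """Emission grid in nm (consecutive integers)."""
        return np.arange(self.emission_start_nm, EMISSION_END_NM + 1)


@dataclass
class PollenLoadSpectra:
    """A load's six emission spectra plus its species label.

    ``spectra`` maps excitation wavelength (nm) to :class:`EmissionSpectrum`.
    ``tone`` is optional descriptive metadata and is never used as a feature.
    """

    load_id: str
    species: str
    spectra: dict[int, EmissionSpectrum] = field(default_factory=dict)
    tone: Optional[str] = None


@dataclass
class SpectralSignature:
    """The 1381-value concatenation of a load's six spectra (L1 block first)."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != len(self.names):
            raise ValidationError(
                f"signature has {self.values.size} values but {len(self.names)} names"
            )


@dataclass
class AnalyserFeatures:
    """The analyser's 18 channel means, in canonical 365r..625b order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (18,):
            raise ValidationError(
                f"analyser features must have exactly 18 entries, got {self.values.shape}"
            )

    names: tuple[str, ...] = ANALYSER_FEATURE_NAMES

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "AnalyserFeatures":
        missing = [n for n in ANALYSER_FEATURE_NAMES if n not in mapping]
        if missing:
            raise ValidationError(f"missing analyser features: {missing}")
        extra = [n for n in mapping if n not in ANALYSER_FEATURE_NAMES]
        if extra:
            raise ValidationError(f"unknown analyser features: {extra}")
        return cls(np.array([float(mapping[n]) for n in ANALYSER_FEATURE_NAMES]))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ANALYSER_FEATURE_NAMES, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[ANALYSER_FEATURE_NAMES.index(name)])
        except ValueError:
            raise KeyError(name) from None


@dataclass
class AnalyserRecord:
    """One load's analyser measurement row."""

    load_id: str
    species: str
    features: AnalyserFeatures
    tone: Optional[str] = None


@dataclass
class AnalyserImageSet:
    """Six RGB rasters for one load, keyed by excitation wavelength.

    Planes are float64 in [0, 255]; quantisation to 8-bit happens only when
    writing PNG, so noise-free renders stay exact in memory.
    ``geometry`` may carry the true disc centre/radius for synthetic fixtures.
    """

    images: dict[int, np.ndarray]
    geometry: Optional[dict] = None

    def __post_init__(self) -> None:
        if set(self.images) != set(EXCITATION_WAVELENGTHS):
            raise ValidationError(
                f"image set must contain exactly the six excitations "
                f"{EXCITATION_WAVELENGTHS}, got {sorted(self.images)}"
            )
        shapes = set()
        for exc, img in self.images.items():
            arr = np.asarray(img, dtype=np.float64)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise ValidationError(f"{exc} nm image must be H x W x 3, got {arr.shape}")
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError(f"{exc} nm image has values outside [0, 255]")
            self.images[exc] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValidationError(f"all six images must share dimensions, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        h, w, _ = next(iter(self.images.values())).shape
        return h, w


SpectroRecord = PollenLoadSpectra
Record = Union[PollenLoadSpectra, AnalyserRecord]


@dataclass
class Dataset:
    """A homogeneous collection of per-load records for one modality."""

    records: list[Record]
    modality: str  # "spectroscopy" | "analyser"
    provenance: str = "file"  # "file" | "synthetic"

    def __post_init__(self) -> None:
        if self.modality not in ("spectroscopy", "analyser"):
            raise UsageError(f"unknown modality {self.modality!r}")
        want = PollenLoadSpectra if self.modality == "spectroscopy" else AnalyserRecord
        for rec in self.records:
            if not isinstance(rec, want):
                raise ValidationError(
                    f"{self.modality} dataset cannot hold a {type(rec).__name__}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def load_ids(self) -> list[str]:
        return [r.load_id for r in self.records]

    @property
    def species_labels(self) -> list[str]:
        """Sorted unique species labels."""
        return sorted({r.species for r in self.records})

    def subset(self, species: Iterable[str]) -> "Dataset":
        keep = set(species)
        return Dataset(
            records=[r for r in self.records if r.species in keep],
            modality=self.modality,
            provenance=self.provenance,
        )


def parse_feature_name(name: str) -> tuple[str, int, Optional[str]]:
    """Parse a feature name into (modality, excitation_nm, detail).

    Spectroscopy names 'Lk_λ' return ('spectroscopy', excitation_nm,
    emission_nm as str); analyser names '365r' return ('analyser',
    excitation_nm, channel letter).
    """
    m = _SPECTRO_NAME_RE.match(name)
    if m:
        exc = EXCITATION_WAVELENGTHS[int(m.group(1)) - 1]
        emission = int(m.group(2))
        if not emission_start_nm(exc) <= emission <= EMISSION_END_NM:
            raise ValidationError(
                f"feature {name!r}: emission {emission} nm outside the "
                f"{emission_start_nm(exc)}-{EMISSION_END_NM} nm grid"
            )
        return "spectroscopy", exc, str(emission)
    m = _ANALYSER_NAME_RE.match(name)
    if m and int(m.group(1)) in EXCITATION_WAVELENGTHS:
        return "analyser", int(m.group(1)), m.group(2)
    raise ValidationError(f"unrecognised feature name {name!r}")


def validate_record(record: PollenLoadSpectra) -> list[str]:
    """Check a spectroscopy record against its invariants.

    Returns a list of human-readable violations (empty iff the record is
    well-formed). Violations are data, not exceptions: readers collect them
    per load and report them together.
    """
    violations: list[str] = []
    if not record.species:
        violations.append("species: must be non-empty")
    if record.tone is not None and record.tone not in TONES:
        violations.append(f"tone: {record.tone!r} not in {TONES}")
    missing = [exc for exc in EXCITATION_WAVELENGTHS if exc not in record.spectra]
    for exc in missing:
        violations.append(f"spectra: missing excitation {exc} nm ({label_for(exc)})")
    extra = [exc for exc in record.spectra if exc not in EXCITATION_WAVELENGTHS]
    for exc in extra:
        violations.append(f"spectra: unsupported excitation {exc} nm")
    for exc in EXCITATION_WAVELENGTHS:
        spec = record.spectra.get(exc)
        if spec is None:
            continue
        label = label_for(exc)
        bad = ~np.isfinite(spec.intensities)
        if bad.any():
            for i in np.flatnonzero(bad):
                wl = spec.emission_start_nm + int(i)
                violations.append(f"intensity: non-finite value at {label}_{wl}")
            continue
        neg = spec.intensities < 0
        if neg.any():
            i = int(np.flatnonzero(neg)[0])
            wl = spec.emission_start_nm + i
            violations.append(
                f"intensity: negative value at {label}_{wl} "
                f"({spec.intensities[i]:g}); {int(neg.sum())} negative sample(s)"
            )
    return violations


@dataclass
class SpeciesSignature:
    """Per-species mean and standard deviation over loads, with the count n."""

    species: str
    mean: np.ndarray
    sd: np.ndarray
    n: int
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.n < 1:
            raise ValidationError("species mean needs n >= 1 loads")
        if (self.sd < 0).any() or not math.isfinite(float(self.sd.sum())):
            raise ValidationError("standard deviations must be finite and non-negative")


@dataclass
class EvaluationReport:
    """Held-out evaluation of one classifier.

    ``confusion`` rows are true labels, columns predicted, in ``labels`` order.
    Per-class recall/precision/F1 follow the standard confusion-matrix
    formulas; ``roc_auc_ovr`` is the unweighted macro mean of one-vs-rest AUCs.
    """

    labels: tuple[str, ...]
    confusion: np.ndarray
    accuracy: float
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    roc_auc_ovr: Optional[float]
    n_test: int

    def per_class(self) -> "object":
        """Per-class metrics as a pandas DataFrame (rows = species)."""
        import pandas as pd

        return pd.DataFrame(
            {"recall": self.recall, "precision": self.precision, "f1": self.f1},
            index=list(self.labels),
        )


@dataclass
class AttributionReport:
    """Shapley attribution of a multiclass model.

    ``phi`` has shape (n_samples, n_features, n_classes); for linear one-vs-rest
    decision functions it satisfies local accuracy exactly:
    sum_j phi[i, j, c] = f_c(x_i) - f_c(background mean).
    """

    feature_names: tuple[str, ...]
    class_names: tuple[str, ...]
    phi: np.ndarray
    mean_abs: np.ndarray  # (n_features, n_classes)
    signed_mean: np.ndarray  # (n_features,)
    top20: tuple[str, ...]
    method: str  # "linear-exact" | "permutation-mc"
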