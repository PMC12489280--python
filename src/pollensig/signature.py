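"""Spectral-signature arithmetic.

Each excitation's emission grid runs from (excitation + 50) nm to 740 nm in
1 nm steps, so its length is 691 - excitation. Over the six excitations the
lengths are 326, 301, 296, 231, 161 and 66, summing to the 1381 features of a
full spectral signature. Signatures concatenate the six blocks in L1..L6 order
with emission ascending inside each block, named "L1_415" ... "L6_740".
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .channels import CHANNELS, EXCITATION_WAVELENGTHS, label_for
from .datamodel import (
    EMISSION_END_NM,
    Dataset,
    EmissionSpectrum,
    PollenLoadSpectra,
    SpeciesSignature,
    SpectralSignature,
    emission_start_nm,
    grid_length,
    validate_record,
)
from .errors import DegenerateInputError, SpeciesLookupError, UsageError, ValidationError

#: Total spectroscopy feature count (sum of the six grid lengths).
N_SPECTRO_FEATURES = sum(grid_length(exc) for exc in EXCITATION_WAVELENGTHS)

#: Cumulative block boundaries of the concatenated signature.
BLOCK_BOUNDARIES = tuple(
    np.cumsum([grid_length(exc) for exc in EXCITATION_WAVELENGTHS]).tolist()
)


def emission_grid(excitation_nm: int) -> np.ndarray:
    """Emission wavelengths (nm) recorded for an excitation.

    Consecutive integers from excitation + 50 to 740 inclusive.
    """
    if excitation_nm not in EXCITATION_WAVELENGTHS:
        raise UsageError(
            f"unsupported excitation {excitation_nm} nm; supported: {EXCITATION_WAVELENGTHS}"
        )
    return np.arange(emission_start_nm(excitation_nm), EMISSION_END_NM + 1)


@lru_cache(maxsize=1)
def signature_feature_names() -> tuple[str, ...]:
    """The 1381 feature names, 'L1_415' first, 'L6_740' last."""
    names: list[str] = []
    for ch in CHANNELS:
        names.extend(f"{ch.label}_{wl}" for wl in emission_grid(ch.wavelength_nm))
    return tuple(names)


def max_normalize(spectrum: EmissionSpectrum) -> EmissionSpectrum:
    """Scale a spectrum so its maximum is 1 (shape-preserving, unitless).

    Used for plotting/averaging exports; classifier inputs are standardized
    separately in :mod:`pollensig.classify`.
    """
    peak = float(np.max(spectrum.intensities))
    if not np.isfinite(peak) or peak <= 0:
        raise DegenerateInputError(
            f"cannot max-normalize a spectrum with max {peak!r} "
            f"(excitation {spectrum.excitation_nm} nm)"
        )
    return EmissionSpectrum(
        excitation_nm=spectrum.excitation_nm,
        intensities=spectrum.intensities / peak,
        bandwidth_nm=spectrum.bandwidth_nm,
    )


def concatenate_signature(record: PollenLoadSpectra) -> SpectralSignature:
    """Concatenate a load's six raw spectra into its 1381-feature signature."""
    violations = validate_record(record)
    if violations:
        raise ValidationError(
            f"record {record.load_id!r} is invalid: " + "; ".join(violations)
        )
    values = np.concatenate(
        [record.spectra[exc].intensities for exc in EXCITATION_WAVELENGTHS]
    )
    return SpectralSignature(values=values, names=signature_feature_names())


def split_signature(signature: SpectralSignature) -> dict[int, EmissionSpectrum]:
    """Inverse of :func:`concatenate_signature`: recover the six spectra exactly."""
    out: dict[int, EmissionSpectrum] = {}
    start = 0
    for exc in EXCITATION_WAVELENGTHS:
        n = grid_length(exc)
        out[exc] = EmissionSpectrum(exc, signature.values[start : start + n])
        start += n
    return out


def signature_table(dataset: Dataset, normalized: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble (X, y) for a spectroscopy dataset.

    X is one row per load with the 1381 named columns (raw intensities, or
    per-spectrum max-normalized if ``normalized``); y maps load_id -> species.
    """
    if dataset.modality != "spectroscopy":
        raise UsageError("signature_table expects a spectroscopy dataset")
    rows = []
    species = []
    ids = []
    for rec in dataset.records:
        if normalized:
            rec = PollenLoadSpectra(
                load_id=rec.load_id,
                species=rec.species,
                spectra={exc: max_normalize(s) for exc, s in rec.spectra.items()},
                tone=rec.tone,
            )
        rows.append(concatenate_signature(rec).values)
        species.append(rec.species)
        ids.append(rec.load_id)
    X = pd.DataFrame(rows, index=ids, columns=list(signature_feature_names()))
    y = pd.Series(species, index=ids, name="species")
    return X, y


def feature_table(dataset: Dataset) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble (X, y) for an analyser dataset (18 named columns)."""
    from .datamodel import ANALYSER_FEATURE_NAMES

    if dataset.modality != "analyser":
        raise UsageError("feature_table expects an analyser dataset")
    ids = [r.load_id for r in dataset.records]
    X = pd.DataFrame(
        [r.features.values for r in dataset.records],
        index=ids,
        columns=list(ANALYSER_FEATURE_NAMES),
    )
    y = pd.Series([r.species for r in dataset.records], index=ids, name="species")
    return X, y


def dataset_xy(dataset: Dataset, normalized: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """(X, y) for either modality."""
    if dataset.modality == "spectroscopy":
        return signature_table(dataset, normalized=normalized)
    return feature_table(dataset)


def species_mean(
    dataset: Dataset, species: str, normalized: bool = False
) -> SpeciesSignature:
    """Elementwise mean and sample sd of one species' loads.

    ``normalized`` applies per-spectrum max-normalization before averaging
    (spectroscopy only); by default raw intensities are averaged.
    """
    sub = dataset.subset([species])
    if len(sub) == 0:
        raise SpeciesLookupError(
            f"species {species!r} not in dataset (has: {dataset.species_labels})"
        )
    X, _ = dataset_xy(sub, normalized=normalized)
    n = len(X)
    mean = X.to_numpy().mean(axis=0)
    sd = X.to_numpy().std(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
    return SpeciesSignature(
        species=species, mean=mean, sd=sd, n=n, names=tuple(X.columns)
    )


def species_mean_table(dataset: Dataset, normalized: bool = False) -> pd.DataFrame:
    """Long table of per-species mean/sd/n for every species in the dataset."""
    frames = []
    for sp in dataset.species_labels:
        sig = species_mean(dataset, sp, normalized=normalized)
        frames.append(
            pd.DataFrame(
                {
                    "species": sp,
                    "feature": list(sig.names),
                    "mean": sig.mean,
                    "sd": sig.sd,
                    "n": sig.n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
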