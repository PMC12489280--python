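"""Readers and writers for spectra tables, analyser feature tables and image sets.

The canonical on-disk spectra format is long CSV with columns
``load_id, species, excitation_nm, emission_nm, intensity`` (an optional
``tone`` column is carried as metadata). A wide dialect (one column per
signature feature) is accepted on read only. Intensities are serialised with
Python's shortest ``repr`` and parsed back in round-trip mode, so
write -> read is bit-exact.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from PIL import Image

from .channels import EXCITATION_WAVELENGTHS
from .datamodel import (
    ANALYSER_FEATURE_NAMES,
    AnalyserFeatures,
    AnalyserImageSet,
    AnalyserRecord,
    Dataset,
    EmissionSpectrum,
    PollenLoadSpectra,
    grid_length,
    parse_feature_name,
    validate_record,
)
from .errors import FormatError, UsageError, ValidationError
from .signature import emission_grid, signature_feature_names

PathLike = Union[str, os.PathLike]

_LONG_COLUMNS = ["load_id", "species", "excitation_nm", "emission_nm", "intensity"]


def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    return repr(float(x))


def read_spectra_table(path: PathLike, dialect: str = "long") -> Dataset:
    """Read a spectra table into a spectroscopy :class:`Dataset`.

    ``dialect='long'`` expects the canonical long format; ``'wide'`` expects
    ``load_id, species`` plus the 1381 signature columns.
    Every load must carry all six complete emission grids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectra table not found: {path}")
    if dialect == "wide":
        return _read_spectra_wide(path)
    if dialect != "long":
        raise UsageError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    has_tone = "tone" in df.columns

    records: list[PollenLoadSpectra] = []
    for load_id, group in df.groupby("load_id", sort=True):
        species = str(group["species"].iloc[0])
        tone = str(group["tone"].iloc[0]) if has_tone and pd.notna(group["tone"].iloc[0]) else None
        spectra: dict[int, EmissionSpectrum] = {}
        for exc in EXCITATION_WAVELENGTHS:
            block = group[group["excitation_nm"] == exc].sort_values("emission_nm")
            expected = emission_grid(exc)
            if len(block) != len(expected) or not np.array_equal(
                block["emission_nm"].to_numpy(), expected
            ):
                raise ValidationError(
                    f"{path}: load {load_id!r} has an incomplete emission grid for "
                    f"excitation {exc} nm ({len(block)}/{len(expected)} samples)"
                )
            intensities = block["intensity"].to_numpy(dtype=np.float64)
            if (intensities < 0).any():
                wl = int(block["emission_nm"].to_numpy()[intensities < 0][0])
                raise ValidationError(
                    f"{path}: load {load_id!r} has a negative intensity at "
                    f"excitation {exc} nm / emission {wl} nm"
                )
            spectra[exc] = EmissionSpectrum(exc, intensities)
        records.append(PollenLoadSpectra(str(load_id), species, spectra, tone))
    return Dataset(records=records, modality="spectroscopy", provenance="file")


def _read_spectra_wide(path: Path) -> Dataset:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("load_id", "species"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column(s) ['{c}']")
    names = signature_feature_names()
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: wide spectra table is missing {len(missing)} signature "
            f"column(s), first: {missing[:3]}"
        )
    has_tone = "tone" in df.columns
    records = []
    for _, row in df.iterrows():
        values = row[list(names)].to_numpy(dtype=np.float64)
        spectra: dict[int, EmissionSpectrum] = {}
        start = 0
        for exc in EXCITATION_WAVELENGTHS:
            n = grid_length(exc)
            if (values[start : start + n] < 0).any():
                raise ValidationError(
                    f"{path}: load {row['load_id']!r} has a negative intensity "
                    f"(excitation {exc} nm)"
                )
            spectra[exc] = EmissionSpectrum(exc, values[start : start + n])
            start += n
        tone = str(row["tone"]) if has_tone and pd.notna(row["tone"]) else None
        records.append(PollenLoadSpectra(str(row["load_id"]), str(row["species"]), spectra, tone))
    return Dataset(records=records, modality="spectroscopy", provenance="file")


def write_spectra_table(dataset: Dataset, path: PathLike) -> None:
    """Write a spectroscopy dataset as canonical long CSV.

    Rows are ordered by (load_id, excitation_nm, emission_nm) ascending;
    intensities keep full precision.
    """
    if dataset.modality != "spectroscopy":
        raise UsageError("write_spectra_table expects a spectroscopy dataset")
    has_tone = any(r.tone is not None for r in dataset.records)
    lines = []
    header = _LONG_COLUMNS + (["tone"] if has_tone else [])
    lines.append(",".join(header))
    for rec in sorted(dataset.records, key=lambda r: r.load_id):
        bad = validate_record(rec)
        if bad:
            raise ValidationError(f"record {rec.load_id!r} is invalid: " + "; ".join(bad))
        tone = rec.tone or ""
        for exc in EXCITATION_WAVELENGTHS:
            spec = rec.spectra[exc]
            for wl, inten in zip(spec.wavelengths, spec.intensities):
                row = f"{rec.load_id},{rec.species},{exc},{wl},{_fmt(inten)}"
                if has_tone:
                    row += f",{tone}"
                lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_feature_table(path: PathLike) -> Dataset:
    """Read an 18-column analyser feature table into a Dataset.

    Requires ``load_id, species`` plus exactly the 18 canonical feature
    columns (any order on disk; normalised to 365r..625b in memory).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("load_id", "species"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column(s) ['{c}']")
    known = {"load_id", "species", "tone"}
    feature_cols = [c for c in df.columns if c not in known]
    missing = [n for n in ANALYSER_FEATURE_NAMES if n not in feature_cols]
    extra = [c for c in feature_cols if c not in ANALYSER_FEATURE_NAMES]
    if missing or extra:
        raise FormatError(
            f"{path}: analyser table must have exactly the 18 canonical feature "
            f"columns; missing={missing} unexpected={extra}"
        )
    has_tone = "tone" in df.columns
    records = []
    for _, row in df.iterrows():
        values = row[list(ANALYSER_FEATURE_NAMES)].to_numpy(dtype=np.float64)
        if (values < 0).any() or (values > 255).any():
            raise ValidationError(
                f"{path}: load {row['load_id']!r} has feature values outside [0, 255]"
            )
        tone = str(row["tone"]) if has_tone and pd.notna(row["tone"]) else None
        records.append(
            AnalyserRecord(str(row["load_id"]), str(row["species"]), AnalyserFeatures(values), tone)
        )
    return Dataset(records=records, modality="analyser", provenance="file")


def write_feature_table(dataset: Dataset, path: PathLike) -> None:
    """Write an analyser dataset as CSV with canonical column order."""
    if dataset.modality != "analyser":
        raise UsageError("write_feature_table expects an analyser dataset")
    has_tone = any(r.tone is not None for r in dataset.records)
    header = ["load_id", "species"] + list(ANALYSER_FEATURE_NAMES) + (
        ["tone"] if has_tone else []
    )
    lines = [",".join(header)]
    for rec in sorted(dataset.records, key=lambda r: r.load_id):
        row = [rec.load_id, rec.species] + [_fmt(v) for v in rec.features.values]
        if has_tone:
            row.append(rec.tone or "")
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_image_set(image_set: AnalyserImageSet, directory: PathLike) -> None:
    """Write the six images as 8-bit PNGs named {excitation}.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for exc, img in image_set.images.items():
        arr = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(directory / f"{exc}.png")


def read_image_set(directory: PathLike) -> AnalyserImageSet:
    """Read a per-load directory of {365,390,395,460,530,625}.png images."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"image directory not found: {directory}")
    images: dict[int, np.ndarray] = {}
    for exc in EXCITATION_WAVELENGTHS:
        p = directory / f"{exc}.png"
        if not p.exists():
            raise FormatError(f"{directory}: missing image {p.name}")
        arr = np.asarray(Image.open(p).convert("RGB"), dtype=np.float64)
        images[exc] = arr
    return AnalyserImageSet(images=images)
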