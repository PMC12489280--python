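"""The six excitation channels of the instrument.

Both the bench spectrofluorometer and the field analyser illuminate the pollen
load with the same six quasi-monochromatic sources: three UV LEDs (365, 390,
395 nm) and the three primaries of an RGB LED (460, 530, 625 nm). Channels are
labelled L1..L6 in ascending wavelength order; spectroscopy feature names are
built from these labels ("L1_415" = emission at 415 nm under 365 nm excitation).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UsageError

#: Excitation wavelengths in nm, ascending; index k corresponds to label L{k+1}.
EXCITATION_WAVELENGTHS: tuple[int, ...] = (365, 390, 395, 460, 530, 625)

#: Excitations whose light the camera also sees as direct reflectance
#: (the RGB-LED primaries); the UV excitations are fluorescence-only.
RGB_EXCITATIONS: tuple[int, ...] = (460, 530, 625)

#: RGB pixel channels in canonical order.
PIXEL_CHANNELS: tuple[str, ...] = ("r", "g", "b")


@dataclass(frozen=True)
class ExcitationChannel:
    """One excitation source: its L-label and wavelength in nm."""

    label: str
    wavelength_nm: int


CHANNELS: tuple[ExcitationChannel, ...] = tuple(
    ExcitationChannel(label=f"L{i + 1}", wavelength_nm=wl)
    for i, wl in enumerate(EXCITATION_WAVELENGTHS)
)

_LABEL_TO_NM = {c.label: c.wavelength_nm for c in CHANNELS}
_NM_TO_LABEL = {c.wavelength_nm: c.label for c in CHANNELS}


def label_for(wavelength_nm: int) -> str:
    """Return the L-label ('L1'..'L6') of a supported excitation wavelength."""
    try:
        return _NM_TO_LABEL[int(wavelength_nm)]
    except KeyError:
        raise UsageError(
            f"unsupported excitation wavelength {wavelength_nm} nm; "
            f"supported: {EXCITATION_WAVELENGTHS}"
        ) from None


def wavelength_for(label: str) -> int:
    """Return the excitation wavelength (nm) for an L-label."""
    try:
        return _LABEL_TO_NM[label]
    except KeyError:
        raise UsageError(f"unknown excitation label {label!r}; expected L1..L6") from None
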