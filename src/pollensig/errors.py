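"""Exception hierarchy for pollensig.

All errors raised on purpose by the package derive from :class:`PollensigError`,
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class PollensigError(Exception):
    """Base class for all pollensig errors."""


class FormatError(PollensigError):
    """A file does not match the expected schema (missing/extra columns, bad names)."""


class ValidationError(PollensigError):
    """Data is schematically fine but violates a domain invariant."""


class UsageError(PollensigError):
    """An operation was called with arguments outside its contract."""


class DegenerateInputError(PollensigError):
    """Input is technically valid but degenerate for the operation (e.g. all-zero spectrum)."""


class NoLoadDetected(PollensigError):
    """Segmentation found no pollen load in the image set."""


class StratificationError(PollensigError):
    """A class is too small to stratify the requested split."""


class GenerationError(PollensigError):
    """The synthetic generator could not satisfy its constraints."""


class SpeciesLookupError(PollensigError):
    """A species label is absent from the dataset."""
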