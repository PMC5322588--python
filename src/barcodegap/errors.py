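"""Exception hierarchy.

All package errors derive from :class:`BarcodeGapError` so callers can catch
one type at pipeline boundaries.  Region-extraction *failure* is deliberately
not an exception — it is a ``None`` return (see ``regions.split_its``).
"""


class BarcodeGapError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(BarcodeGapError, ValueError):
    """Invalid simulation / filter / pipeline configuration."""


class FormatError(BarcodeGapError, ValueError):
    """Malformed input file (duplicate accessions, missing columns, ...)."""


class InputError(BarcodeGapError, ValueError):
    """Invalid in-memory input to an operation (empty sequence, mixed genera, ...)."""


class UndefinedDistanceError(BarcodeGapError, ValueError):
    """A p-distance has no comparable alignment columns."""


class EvaluationError(BarcodeGapError, ValueError):
    """A genus cannot be scored (e.g. no species with >= 2 sequences)."""
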