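"""Exception hierarchy.

All user-facing errors derive from :class:`PresepError` so the CLI can map
them to exit status 1; anything else is treated as an internal error.
"""


class PresepError(Exception):
    """Base class for all errors raised by presep."""


class PropertyTableError(PresepError):
    """A physicochemical scale table is malformed or incomplete."""


class DegenerateScaleError(PropertyTableError):
    """A scale has zero spread across the 20 amino acids."""


class SequenceError(PresepError):
    """A protein sequence fails validation."""


class AlphabetError(SequenceError):
    """Non-standard residue under the strict policy."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position  # 1-based
        super().__init__(
            f"non-standard residue {symbol!r} at position {position}"
        )


class TooShortError(SequenceError):
    """Sequence shorter than the minimum usable length."""


class LagError(PresepError):
    """Correlation lag out of range for the sequence length."""


class DegenerateDenominatorError(PresepError):
    """PseAAC normalising denominator vanished (Type II only)."""


class DatasetError(PresepError):
    """FASTA/label ingestion or filtering failure."""


class ModelError(PresepError):
    """Training or prediction contract violation."""
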