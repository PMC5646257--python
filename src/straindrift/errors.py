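"""Exception hierarchy.

Everything raised intentionally by the package derives from
:class:`StrainDriftError`; the CLI maps these to exit code 3 (data error)
and anything else to 4 (internal error).
"""


class StrainDriftError(Exception):
    """Base class for all errors raised by straindrift."""


class DataError(StrainDriftError):
    """Malformed or inconsistent input data."""


class PatternSyntaxError(DataError):
    """Malformed PROSITE pattern string.

    Carries the 0-based character position of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class UnsupportedVariantError(DataError):
    """Variant allele shape the annotator refuses (length-changing)."""


class CensoredInputError(DataError):
    """Observation below the assay detection limit used where a
    quantified value is required."""
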