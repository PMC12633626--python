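"""Exception hierarchy with stable machine-readable codes.

Every error raised by the library carries a short upper-case ``code`` that the
CLI prints and exits with, so scripted callers can branch on failures without
parsing messages.
"""

from __future__ import annotations


class FtuMaskError(Exception):
    """Base class for all library errors."""

    code: str = "ERROR"

    def __init__(self, message: str = ""):
        self.message = message
        super().__init__(f"{self.code}: {message}" if message else self.code)


class FormatError(FtuMaskError):
    code = "FORMAT_ERROR"


class DimensionError(FtuMaskError):
    code = "DIMENSION_ERROR"


class BoundsError(FtuMaskError):
    code = "BOUNDS_ERROR"


class ManifestError(FtuMaskError):
    code = "MANIFEST_ERROR"


class ParseError(FtuMaskError):
    code = "PARSE_ERROR"


class StyleError(FtuMaskError):
    code = "STYLE_ERROR"


class UnknownTypeError(FtuMaskError):
    code = "UNKNOWN_TYPE"


class UnknownFeatureError(FtuMaskError):
    code = "UNKNOWN_FEATURE"


class EmptyChannelError(FtuMaskError):
    code = "EMPTY_CHANNEL"


class PlacementError(FtuMaskError):
    code = "PLACEMENT_ERROR"


class InsufficientDataError(FtuMaskError):
    code = "INSUFFICIENT_DATA"


class WriteError(FtuMaskError):
    code = "IO_ERROR"
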