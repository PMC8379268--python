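"""Exception hierarchy shared across the package."""


class CbciError(Exception):
    """Base class for all package errors."""


class ParameterError(CbciError, ValueError):
    """An impossible or inconsistent parameter combination."""


class FormatError(CbciError, ValueError):
    """A file or record violating one of the documented data contracts."""


class MissingChannelError(CbciError, KeyError):
    """A required electrode is absent from a recording."""


class MissingFeatureError(CbciError, ValueError):
    """A feature schema demands an input that was not provided."""


class InsufficientDataError(CbciError, ValueError):
    """Too few trials (or too few per class) to fit a model."""
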