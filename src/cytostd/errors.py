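"""Exception hierarchy shared across the cytostd modules."""


class CytostdError(Exception):
    """Base class for all cytostd errors."""


class FormatError(CytostdError):
    """A byte stream or text document violates the file format it claims."""


class ValidationError(CytostdError):
    """An in-memory object violates its own invariants."""


class UnsupportedFeatureError(CytostdError):
    """A format feature that is recognized but deliberately not implemented."""


class ChannelError(CytostdError):
    """A referenced channel ($PnN short name) does not exist in a dataset."""


class GateReferenceError(CytostdError):
    """A gate, transform or matrix reference does not resolve, or cycles."""


class MappingError(CytostdError):
    """A detector/channel name mapping could not be established."""


class IntegrityError(CytostdError):
    """Container contents disagree with their table of contents or checksums."""


class NumericalError(CytostdError):
    """A linear-algebra step failed (e.g. a singular spillover matrix)."""
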