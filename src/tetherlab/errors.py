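"""Exception hierarchy shared across tetherlab."""


class TetherlabError(Exception):
    """Base class for all tetherlab errors."""


class UnknownDeviceError(TetherlabError):
    """A frame references a device_id absent from the governing map."""


class PayloadSizeError(TetherlabError):
    """Payload length disagrees with a fixed-size device descriptor."""


class PayloadOverflowError(TetherlabError):
    """Payload exceeds the 65,535-byte limit of the 2-byte length field."""


class IncompleteFrameError(TetherlabError):
    """Byte buffer ends before a complete frame; recoverable — wait for more bytes."""


class StreamFormatError(TetherlabError):
    """Stream file lacks the expected magic prefix or is structurally invalid."""


class BlockOverflowError(TetherlabError):
    """A single encoded frame is larger than the configured block size."""


class IllConditionedError(TetherlabError):
    """Triangulation rays are too close to parallel for a stable solution."""


class InsufficientDataError(TetherlabError):
    """Not enough input samples/stations/time bins for the requested operation."""


class ConfigError(TetherlabError):
    """Run configuration violates the schema; message names the offending key."""


class DomainError(TetherlabError, ValueError):
    """An argument is outside the documented domain of an operation."""
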