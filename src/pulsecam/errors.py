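"""Exception hierarchy for the pipeline.

A missing face is NOT an exception: detectors return ``None`` and the
pipeline skips the frame without touching the buffer. Exceptions are
reserved for contract violations and unusable inputs.
"""


class PulsecamError(Exception):
    """Base class for all package errors."""


class SourceError(PulsecamError):
    """Video source cannot be opened or decoded."""


class EmptyStreamError(SourceError):
    """A source opened successfully but yielded zero frames."""


class StreamOrderError(PulsecamError):
    """Frame indices pushed out of order into a buffer."""


class BandError(PulsecamError):
    """A frequency band contains no spectral bins at the given resolution."""


class SignalError(PulsecamError):
    """A signal-processing precondition failed (too short, zero norm, ...)."""


class AdapterContractError(PulsecamError):
    """A detection adapter returned output violating its contract."""


class SpecError(PulsecamError):
    """Invalid synthetic-video or pipeline configuration."""
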