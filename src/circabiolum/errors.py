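"""Exception types shared across the package."""


class CircabiolumError(Exception):
    """Base class for package errors."""


class InvalidProtocolError(CircabiolumError):
    """Temperature protocol violates its invariants."""


class NoRhythmError(CircabiolumError):
    """No spectral peak found in the circadian band."""


class TrackingLostError(CircabiolumError):
    """Spot tracker found no reachable candidate in some frame."""

    def __init__(self, frame: int, message: str | None = None):
        self.frame = frame
        super().__init__(message or f"tracking lost at frame {frame}")


class SegmentationError(CircabiolumError):
    """Protocol does not fit inside the recording span."""
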