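"""Exception types shared across the package."""


class LstmkfError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(LstmkfError, ValueError):
    """A scalar/config parameter is outside its admissible range."""


class NoDepthError(LstmkfError):
    """A depth patch contains no valid pixels; no range can be measured."""


class InvalidPoseError(LstmkfError, ValueError):
    """An observer pose rotation is not orthonormal within tolerance."""


class DimensionError(LstmkfError, ValueError):
    """Array shapes are inconsistent with the declared state dimension."""
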