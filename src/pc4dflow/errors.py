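"""Exception hierarchy for the pc4dflow pipeline.

All errors derive from :class:`Pc4dFlowError` (a ``ValueError``) so callers can
catch pipeline problems with a single except clause while still distinguishing
the failing stage.
"""


class Pc4dFlowError(ValueError):
    """Base class for all pc4dflow errors."""


class GeometryError(Pc4dFlowError):
    """Objects (tube, plane, emitter) do not fit or intersect the volume."""


class TimingError(Pc4dFlowError):
    """Frame timing is invalid (too few frames, non-increasing triggers)."""


class ParameterError(Pc4dFlowError):
    """A processing parameter is out of its documented range."""


class FormatError(Pc4dFlowError):
    """On-disk dataset is malformed or internally inconsistent."""


class CorrectionError(Pc4dFlowError):
    """Background correction cannot proceed (empty/degenerate static mask)."""


class SegmentationError(Pc4dFlowError):
    """Vessel segmentation produced an empty or unusable region."""
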