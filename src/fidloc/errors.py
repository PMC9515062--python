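"""Exception hierarchy for fidloc."""


class FidlocError(Exception):
    """Base class for all fidloc errors."""


class GeometryError(FidlocError):
    """Invalid or ambiguous marker geometry."""


class VolumeIOError(FidlocError):
    """A volume could not be read or written."""


class NoForegroundError(FidlocError):
    """A volume contains no intensity structure above background."""


class NoisyVolumeError(FidlocError):
    """Candidate extraction produced an implausible number of components."""


class DegenerateGeometryError(FidlocError):
    """Point set too degenerate (collinear/coincident) for a rigid fit."""


class RenderError(FidlocError):
    """Synthetic rendering request is inconsistent (e.g. feature truncated)."""
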