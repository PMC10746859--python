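"""Exception hierarchy.

Every failure mode that callers are expected to branch on gets its own
class; CLI maps them to categorized non-zero exit codes.
"""


class MolshotsError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(MolshotsError):
    """Input file is in a format we deliberately do not read (e.g. .bcif)."""


class MalformedCIFError(MolshotsError):
    """The CIF text could not be parsed."""


class NoCoordinatesError(MolshotsError):
    """A CIF file without an ``atom_site`` category carries no coordinates."""


class UnknownAssemblyError(MolshotsError):
    """Requested assembly id is not defined in the structure."""


class EmptyStructureError(MolshotsError):
    """Structure has no models or no atoms where at least one is required."""


class DegenerateGeometryError(MolshotsError):
    """Coordinate set too small for the requested geometric operation."""


class SceneTypeError(MolshotsError):
    """Requested scene type does not exist or is not applicable to the mode."""


class PLDDTRangeError(MolshotsError):
    """Confidence value outside the valid [0, 100] range."""


class AnnotationError(MolshotsError):
    """Annotation file unreadable or not JSON."""


class RenderError(MolshotsError):
    """Invalid render request (e.g. upscaling in :func:`downscale`)."""


class ConfigError(MolshotsError):
    """Invalid run configuration (e.g. no coordinate source)."""
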