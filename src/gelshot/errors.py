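"""Exception hierarchy.

All gelshot errors derive from :class:`GelshotError` so callers can catch
one type at pipeline level; the subclasses mirror the failure modes of a
QA run (bad files, inconsistent geometry, failed detection, bad usage).
"""


class GelshotError(Exception):
    """Base class for all gelshot errors."""


class FormatError(GelshotError):
    """A file or series does not conform to the expected format."""


class GeometryError(GelshotError):
    """Volumes, VOIs or sampling geometry are inconsistent."""


class UsageError(GelshotError, ValueError):
    """Invalid parameters or configuration."""


class DomainError(GelshotError, ValueError):
    """A physical quantity is outside its valid domain (e.g. negative dose)."""


class DetectionError(GelshotError):
    """Beam tracks or fiducial markers could not be found."""


class DegenerateGeometryError(GelshotError):
    """The line bundle does not determine a finite isocenter (e.g. all parallel)."""
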