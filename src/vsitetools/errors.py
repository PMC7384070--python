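"""Exception hierarchy for vsitetools.

Every error raised by the package derives from :class:`VsiteToolsError`, so
callers (in particular the command-line driver) can distinguish expected
domain failures from genuine bugs.
"""


class VsiteToolsError(Exception):
    """Base class for all vsitetools errors."""


class FileFormatError(VsiteToolsError):
    """A file could not be parsed; the message names the file and line."""


class ForceFieldError(VsiteToolsError):
    """A force-field directory is missing, incomplete, or inconsistent."""


class DuplicateDefinitionError(ForceFieldError):
    """Two conflicting parameter entries exist for the same type tuple."""


class AmbiguousLookupError(ForceFieldError):
    """A wildcard lookup matched several equally specific, different entries."""


class TopologyError(VsiteToolsError):
    """A molecule topology or residue template is malformed."""


class UnknownAtomTypeError(VsiteToolsError):
    """An atom type used by a topology is defined nowhere."""


class MissingParameterError(VsiteToolsError):
    """A bonded parameter needed for geometry reconstruction is unavailable."""


class InconvertibleDihedralError(VsiteToolsError):
    """A torsion potential cannot be expressed in the requested form."""


class GeometryError(VsiteToolsError):
    """Degenerate coordinates (e.g. collinear atoms) make a quantity undefined."""
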