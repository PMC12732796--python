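"""Exception hierarchy.

Every failure mode named in a module contract maps to one class here, so
callers (and the CLI exit-code table) can dispatch on type rather than on
message text.
"""


class GikError(Exception):
    """Base class for all package errors."""


class InputError(GikError):
    """Bad input data: unparsable file, empty file, duplicate ids."""


class FormatError(InputError):
    """A structure file does not parse under the named standard."""


class EmptyInputError(InputError):
    """An input file or set is empty."""


class CongruenceError(InputError):
    """Frame/topology atom counts disagree."""


class SelectionError(GikError):
    """A selection expression references an unknown chain, label or field."""


class ParameterError(GikError):
    """A parameter violates its precondition (cutoff, block size, fraction)."""


class GeometryError(GikError):
    """Too few points, or a required atom is missing."""


class AtomMissingError(GeometryError):
    """A named atom (e.g. CA, the donor hydrogen) is absent."""


class MappingError(GikError):
    """Generic-numbering lookup failure (unmapped residue or label)."""


class AlignmentError(GikError):
    """Alignment-based annotation failed (format or identity threshold)."""


class AnalysisError(GikError):
    """An analysis has no frames/data to operate on."""


class GenerationError(GikError):
    """A synthetic scenario is internally contradictory."""
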