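"""Exception hierarchy shared across the toolkit."""


class KirdockError(Exception):
    """Base class for all toolkit errors."""


class StructureParseError(KirdockError):
    """A file could not be interpreted as a macromolecular structure."""


class EmptyStructureError(StructureParseError):
    """A parsed file contained no atoms."""


class AddressingError(KirdockError):
    """A chain/residue address or segment span could not be resolved."""


class ShapeError(KirdockError):
    """Coordinate arrays have incompatible shapes or counts."""


class SpliceError(KirdockError):
    """Replacement sequence incompatible with the target span."""


class MutationError(KirdockError):
    """A mutation's expected source residue does not match the sequence."""


class AssemblyError(KirdockError):
    """Oligomer assembly preconditions violated."""


class GridError(KirdockError):
    """Score-grid construction or correlation preconditions violated."""


class ParameterError(KirdockError):
    """An out-of-range or inconsistent parameter value."""
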