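"""Exception hierarchy shared across the package."""


class GraphMQAError(Exception):
    """Base class for all package-specific errors."""


class StructureIOError(GraphMQAError):
    """A PDB file could not be read or contains no usable residues."""


class EmptyStructureError(StructureIOError):
    """No residue survived backbone filtering."""


class GeometryError(GraphMQAError):
    """Degenerate geometry (collinear atoms, ill-defined frame)."""


class AlignmentError(GraphMQAError):
    """Model and reference structures cannot be paired residue-by-residue."""


class DegenerateInputError(GraphMQAError):
    """Input too small or otherwise outside the operation's domain."""


class ContractError(GraphMQAError):
    """Shapes or values violate an operation's calling contract."""


class ConfigError(GraphMQAError):
    """Invalid run/training configuration."""


class UnsupportedLengthError(GraphMQAError):
    """Sequence too long for the embedding split rule."""
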