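"""Exception hierarchy for ghmotif."""


class GHMotifError(Exception):
    """Base class for all ghmotif errors."""


class EmptyInputError(GHMotifError):
    """An input file or container held no usable records."""


class AlignmentFormatError(GHMotifError):
    """A multiple alignment violated a format invariant (e.g. ragged rows)."""


class MatrixFormatError(GHMotifError):
    """A similarity/distance matrix file was malformed."""


class StructureFormatError(GHMotifError):
    """A coordinate file could not be interpreted as required."""


class ChainNotFoundError(StructureFormatError):
    """Requested chain absent from a structure; message lists available chains."""


class ConfigError(GHMotifError):
    """A family configuration violated its constraints."""
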