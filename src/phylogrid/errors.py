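"""Exception hierarchy shared across the package."""


class PhylogridError(Exception):
    """Base class for all package-specific errors."""


class NewickFormatError(PhylogridError, ValueError):
    """Malformed Newick input (unbalanced parentheses, missing lengths, ...)."""


class MatrixFormatError(PhylogridError, ValueError):
    """Malformed community-matrix or genus-map CSV."""


class InputValidationError(PhylogridError, ValueError):
    """Inputs violate a structural invariant (duplicate labels, bad entry)."""


class UndefinedResultError(PhylogridError, ValueError):
    """A statistic is undefined for the given input (e.g. MPD of one taxon)."""
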