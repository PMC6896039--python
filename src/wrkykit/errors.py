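"""Exception hierarchy shared across the toolkit."""


class WrkyKitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(WrkyKitError):
    """Malformed input file (FASTA, GFF3, TSV...)."""


class ValidationError(WrkyKitError):
    """Structurally parseable input violating a domain invariant."""


class ClassificationError(WrkyKitError):
    """A member cannot be assigned to a group by the domain rule."""


class NumericalError(WrkyKitError):
    """A numerical routine failed to converge or is undefined."""
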