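"""Exception hierarchy shared across the package."""


class SquatmonError(Exception):
    """Base class for all package errors."""


class FormatError(SquatmonError, ValueError):
    """A file does not conform to the expected dialect (bad header/columns)."""


class DataError(SquatmonError, ValueError):
    """Well-formed file with invalid content (e.g. non-monotone timestamps)."""


class AlignmentError(SquatmonError, ValueError):
    """Streams or tracks that cannot be brought onto a common grid."""


class ParameterError(SquatmonError, ValueError):
    """An argument outside its documented domain."""


class ContractError(SquatmonError, ValueError):
    """Mismatch between a model bundle and the data it is applied to."""
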