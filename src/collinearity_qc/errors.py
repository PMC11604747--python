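"""Exception hierarchy shared across the package."""


class CollinearityQCError(Exception):
    """Base class for all errors raised by collinearity-qc."""


class InputError(CollinearityQCError):
    """An input file is missing, unreadable, or malformed."""


class EmptyAnnotationError(InputError):
    """A GFF3 file yielded zero gene features after filtering."""


class NoSharedGenesError(CollinearityQCError):
    """Reference and target annotations share no gene identifiers."""


class ConfigError(CollinearityQCError):
    """A configuration value is outside its valid domain."""


class OutputError(CollinearityQCError):
    """An output path could not be written."""
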