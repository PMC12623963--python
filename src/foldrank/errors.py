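"""Exception hierarchy.

Everything raised on bad user input derives from :class:`FoldrankError`
so the CLI can map library failures to exit code 1 while genuine usage
errors (bad flags) stay with click's exit code 2.
"""


class FoldrankError(Exception):
    """Base class for all foldrank data/validation errors."""


class ParseError(FoldrankError):
    """A file could not be parsed (malformed record, bad dialect)."""


class ChainNotFoundError(FoldrankError):
    """Requested chain absent from a PDB file."""


class IntegrityError(FoldrankError):
    """Table-level inconsistency, e.g. duplicate model identifiers."""


class ArgumentError(FoldrankError):
    """Invalid argument combination passed to a library operation."""


class ConfigError(FoldrankError):
    """A configuration references unknown columns, domains or keys."""


class AssemblyError(FoldrankError):
    """Fragment assembly preconditions violated (overlap, coverage)."""


class GenerationError(FoldrankError):
    """A synthetic-data generator could not satisfy its constraints."""
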