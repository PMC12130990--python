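"""Exception hierarchy.

All package errors derive from :class:`NucmergeError` so callers (and the
CLI) can distinguish input problems from genuine bugs.
"""


class NucmergeError(Exception):
    """Base class for all package errors."""


class FormatError(NucmergeError):
    """A file does not parse as the documented dialect."""


class ValidationError(NucmergeError):
    """A record or container violates a stated invariant."""


class SchemaError(NucmergeError):
    """A type schema is malformed or a label is unmapped."""


class ConfigError(NucmergeError):
    """A configuration value is out of range or inconsistent."""


class ContractError(NucmergeError):
    """An operation was called outside its precondition."""


class GenerationError(NucmergeError):
    """Synthetic data generation could not satisfy its constraints."""
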