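"""Exception hierarchy.

Errors are split by who has to act on them: configuration errors mean the
caller's parameters are wrong, data-integrity errors mean the table itself
violates a contract, format errors mean an external resource file is
malformed, pipeline-order errors mean a prerequisite stage has not been run.
"""


class GirasolError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GirasolError):
    """A parameter value or combination of parameters is invalid."""


class UndefinedInputError(GirasolError):
    """An index is mathematically undefined for the given input (e.g. an
    empty string where a length appears in a denominator)."""


class DataIntegrityError(GirasolError):
    """The input table violates a structural contract (missing attempt
    columns, duplicate group/attempt keys, match string of the wrong
    length, ...)."""


class FormatError(GirasolError):
    """An external resource file (wordlist, frequency lexicon, embedding
    table) could not be parsed."""


class PipelineOrderError(GirasolError):
    """A stage was invoked before the stage that produces its inputs."""


class SimulationError(GirasolError):
    """The response simulator could not satisfy a category's defining
    constraints within its retry budget."""
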