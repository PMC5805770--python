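"""Exception hierarchy for readforest."""


class ReadForestError(Exception):
    """Base class for all readforest errors."""


class ParseError(ReadForestError):
    """A FASTA/FASTQ record could not be parsed."""


class FixedLengthError(ReadForestError):
    """Input reads are not all of the same length L."""


class AlphabetError(ReadForestError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class EmptyInputError(ReadForestError):
    """The input file contains no sequence records."""


class ParameterError(ReadForestError, ValueError):
    """An algorithm parameter is out of its valid range."""


class ContainerFormatError(ReadForestError):
    """The container's magic number or version is not recognized."""


class ContainerIntegrityError(ReadForestError):
    """The container is structurally valid but internally inconsistent."""
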