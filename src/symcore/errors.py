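"""Exception hierarchy shared across the package."""


class SymcoreError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SymcoreError, ValueError):
    """An argument is outside its documented domain."""


class FastaFormatError(SymcoreError, ValueError):
    """A sequence file could not be parsed; message carries path and line."""


class CodonAlignmentError(SymcoreError, ValueError):
    """A gene pair cannot be codon-aligned (frame problems, internal stops)."""


class AlignmentFilterError(CodonAlignmentError):
    """A codon alignment survived with too few columns to be usable."""


class PipelineStageError(SymcoreError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
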