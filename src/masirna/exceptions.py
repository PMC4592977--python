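"""Exception hierarchy shared across the pipeline."""


class MasirnaError(Exception):
    """Base class for all package errors."""


class FormatError(MasirnaError, ValueError):
    """Malformed input file (FASTA/FASTQ/BED/GFF/alignment)."""


class ParameterError(MasirnaError, ValueError):
    """A parameter violates an operation's preconditions."""


class StageError(MasirnaError, RuntimeError):
    """A pipeline stage failed; the stage name is carried in ``stage``."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
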