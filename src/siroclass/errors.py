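"""Exception types shared across the package."""


class SiroclassError(Exception):
    """Base class for all errors raised by this package."""


class FastaError(SiroclassError):
    """Malformed FASTA input (empty file, duplicate ids, bad residues)."""


class AlignmentError(SiroclassError):
    """Invalid input to an alignment operation."""


class PhyloError(SiroclassError):
    """Invalid input to a distance/tree operation."""


class PipelineStageError(SiroclassError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
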