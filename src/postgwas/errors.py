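"""Exception hierarchy shared across the package.

Each class maps onto a process exit code used by the command-line
interface: validation errors exit 2, format errors 3, simulation errors 4.
"""


class PostGwasError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(PostGwasError):
    """An input value violates a documented precondition."""

    exit_code = 2


class SnpLookupError(ValidationError):
    """A SNP identifier is not present in the haplotype panel."""


class MonomorphicSnpError(ValidationError):
    """LD is undefined for a monomorphic site (zero variance)."""


class HarmonizationError(ValidationError):
    """Allele configurations of two records cannot be reconciled."""


class FormatError(PostGwasError):
    """A file does not conform to the expected dialect."""

    exit_code = 3


class PackagingError(FormatError):
    """A bundled fixture failed its checksum; the installation is corrupt."""


class SimulationError(PostGwasError):
    """A stochastic generator could not satisfy its sampling quota."""

    exit_code = 4


class StageError(PostGwasError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
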