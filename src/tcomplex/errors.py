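"""Exception hierarchy.

Configuration problems (bad input files, bad chain/range specs) are kept
separate from computation failures (degenerate geometry, failed fits) so the
CLI can map them to distinct exit codes.
"""


class TcomplexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TcomplexError):
    """The run configuration or assignment spec is invalid."""


class ComputationError(TcomplexError):
    """A computation failed on valid input."""


class DegenerateStructureError(ComputationError):
    """A subunit or subdomain has too few / collinear / isotropic atoms."""


class NativeClashError(ComputationError):
    """The native configuration violates the clash rule."""


class EmptyInterfaceError(ComputationError):
    """No cross-subunit contacts under the interface cutoff."""


class SamplingError(ComputationError):
    """Configuration sampling aborted (e.g. clash-free fraction too low)."""


class FitError(ComputationError):
    """The two-state transition fit failed or is implausible."""


class InsufficientDataError(ComputationError):
    """Not enough populated bins to build or fit the transition profile."""


class StageError(TcomplexError):
    """An end-to-end pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
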