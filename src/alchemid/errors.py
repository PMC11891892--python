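"""Exception hierarchy for the intermediate generator."""


class AlchemidError(Exception):
    """Base class for all package errors."""


class CoreTooSmall(AlchemidError):
    """The maximum common substructure is smaller than the configured minimum."""


class McsTimeout(AlchemidError):
    """The MCS search exceeded its time budget."""


class RingCutRequired(AlchemidError):
    """A substituent excision would require cutting a ring bond that the
    fused-site grouping failed to freeze (indicates a grouping bug)."""


class UnsupportedBond(AlchemidError):
    """A core/substituent crossing bond has order > 1 (or is aromatic) at a
    differing site; cutting it would create ambiguous valence or stereo."""


class AssemblyFailure(AlchemidError):
    """Reattachment produced a molecule that failed valence or aromaticity
    sanitization.  Recorded per-candidate, never raised by the orchestrator."""


class InfeasibleSpec(AlchemidError):
    """A synthetic-fixture request cannot be realized with the given pool."""


class ParseError(AlchemidError):
    """An input file could not be read at all."""


class EmptyAfterFilter(AlchemidError):
    """Every candidate was removed by the heavy-atom filter."""


class BackendUnavailable(AlchemidError):
    """A shape-similarity backend was requested but none is registered."""


class WindowTooLong(AlchemidError):
    """A free-energy time series is shorter than the convergence window."""
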