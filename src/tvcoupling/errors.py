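"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter set violates its invariants (e.g. breakpoint ordering)."""


class IntegrationError(RuntimeError):
    """The fixed-step integrator produced a non-finite state."""


class ZeroNormError(ValueError):
    """A similarity index was requested for a coupling function of zero L2 norm."""


class PreconditionError(ValueError):
    """An operation's mathematical precondition does not hold for the given inputs."""
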