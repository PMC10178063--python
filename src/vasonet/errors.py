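"""Exception hierarchy shared across the package."""


class VasonetError(Exception):
    """Base class for all package-specific errors."""


class FixtureNotFoundError(VasonetError):
    """Unknown benchmark model identifier."""


class NetworkFileError(VasonetError):
    """A network or sample file could not be parsed; message carries context."""


class ValidationFailure(VasonetError):
    """An operation required a valid network but validation found violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"network validation failed: {lines}")


class SolverError(VasonetError):
    """The nodal pressure system could not be solved (e.g. no pressure reference)."""


class PlacementError(VasonetError):
    """A sprout could not be placed without coinciding with existing geometry."""
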