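"""Exception types shared across the package."""


class MdfconnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MdfconnError, ValueError):
    """Invalid parameter values or malformed run configuration."""


class SWCParseError(MdfconnError, ValueError):
    """Malformed SWC input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InfeasibleDensityError(MdfconnError, RuntimeError):
    """Soma placement cannot satisfy the minimum-distance constraint."""


class InvalidNetworkError(MdfconnError, ValueError):
    """Network violates structural requirements (e.g. an edge with zero weight)."""


class UndefinedEfficiencyError(MdfconnError, ZeroDivisionError):
    """Efficiency normalizer E(G_ideal) vanishes."""


class UndefinedCostError(MdfconnError, ZeroDivisionError):
    """Cost normalizer (total weight) vanishes."""
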