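"""Exception taxonomy shared across the package.

``DomainError`` flags arguments outside an operation's mathematical domain
(negative times, negative injury values).  ``ConfigError`` flags structurally
invalid configuration (unknown signal kinds, infeasible prior moments).
``ContractError`` flags call-sequence violations (using a disabled receptor
extension).  ``NumericalError`` flags non-finite values produced during
integration, and carries the offending time when known.
"""


class DomainError(ValueError):
    """Argument outside the mathematical domain of an operation."""


class ConfigError(ValueError):
    """Structurally invalid configuration."""


class ContractError(RuntimeError):
    """Operation called in a state its contract forbids."""


class NumericalError(ArithmeticError):
    """Non-finite value encountered during numerical evaluation."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time
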