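"""Exception hierarchy shared across the package."""


class SucrokinError(Exception):
    """Base class for all package errors."""


class DomainError(SucrokinError, ValueError):
    """A quantity left its mathematically admissible domain
    (negative concentration, zero volume fraction, ...)."""


class InputError(SucrokinError, ValueError):
    """Structurally invalid input (missing species, mismatched tables, ...)."""


class ConfigError(SucrokinError, ValueError):
    """Invalid or incomplete configuration."""


class UndefinedElasticityError(SucrokinError, ZeroDivisionError):
    """Scaled elasticity requested at a point where the metabolic
    function vanishes."""


class IntegrationError(SucrokinError, RuntimeError):
    """ODE integration failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
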