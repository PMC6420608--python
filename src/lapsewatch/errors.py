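"""Exception types shared across lapsewatch modules."""


class LapsewatchError(Exception):
    """Base class for all lapsewatch errors."""


class ValidationError(LapsewatchError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(LapsewatchError, ValueError):
    """A file or table does not match the expected layout."""


class CalibrationError(LapsewatchError, RuntimeError):
    """A model fit failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateUpdateError(LapsewatchError, RuntimeError):
    """A posterior update annihilated all probability mass."""
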