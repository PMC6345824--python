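"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter or input field violates its contract.

    Parameters
    ----------
    field : str
        Name of the offending field or argument.
    message : str
        Human-readable description.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ProcessingError(RuntimeError):
    """A derivation could not be completed for a physically meaningful reason.

    Carries a short machine-readable ``code`` (e.g. ``"zeu_below_profile"``,
    ``"profile_too_shallow"``) that orchestration layers record in provenance
    logs instead of crashing.
    """

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(message or code)
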