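"""Exception hierarchy shared across the package."""


class SageScreenError(Exception):
    """Base class for all package-specific errors."""


class InstrumentParseError(SageScreenError):
    """The on-disk instrument document could not be parsed into the data model."""


class InstrumentValidationError(SageScreenError):
    """An instrument violated one or more structural invariants.

    Carries the full issue list so a caller sees every broken reference at once.
    """

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__(
            "instrument failed validation with %d issue(s):\n  - %s"
            % (len(self.issues), "\n  - ".join(self.issues))
        )


class ResponseRangeError(SageScreenError):
    """A response value is outside the item's admissible range or has the wrong type."""


class UnknownItemError(SageScreenError):
    """A response referenced an item that does not exist or is not currently pending."""


class IncompleteResponsesError(SageScreenError):
    """An operation that requires complete responses was given a partial set."""

    def __init__(self, missing_item_ids, context: str = ""):
        self.missing_item_ids = sorted(missing_item_ids)
        msg = "missing responses for: %s" % ", ".join(self.missing_item_ids)
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class UnsupportedModuleError(SageScreenError):
    """A numeric summary score was requested for a module whose screener is not pure Likert."""


class SimulationError(SageScreenError):
    """Infeasible simulation targets (e.g. an impossible kappa/prevalence combination)."""
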