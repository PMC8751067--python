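"""Exception hierarchy for snpanel."""


class SnpanelError(Exception):
    """Base class for all snpanel errors."""


class FormatError(SnpanelError):
    """A file could not be parsed in the expected format."""


class ValidationError(SnpanelError):
    """Inputs violate a documented precondition."""


class EmptyPanelError(SnpanelError):
    """An operation produced or received a panel with no usable markers."""


class UndefinedValueError(SnpanelError):
    """A statistic is undefined for the given input (e.g. all calls missing)."""


class IndistinguishableVarietiesError(ValidationError):
    """Two or more varieties share identical genotypes over every candidate marker."""

    def __init__(self, groups):
        self.groups = [list(g) for g in groups]
        detail = "; ".join(", ".join(g) for g in self.groups)
        super().__init__(
            f"varieties cannot be distinguished by the candidate markers: {detail}"
        )
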