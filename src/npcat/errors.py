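"""Exception hierarchy for the npcat pipeline."""


class NpcatError(Exception):
    """Base class for all npcat errors."""


class ValidationError(NpcatError):
    """An input record, table, or configuration violates its contract."""


class UnclassifiableLesionError(NpcatError):
    """A lesion cannot be assigned an N-P risk label.

    Raised for type-B2 lesions without a measured SUVmax: the combined
    rule requires PET only for B2, so B1/B3 lesions with missing SUV are
    still classifiable.
    """


class SeparationError(NpcatError):
    """Complete or quasi-complete separation in a logistic fit.

    Carries the name of the offending covariate in ``covariate``.
    """

    def __init__(self, covariate: str, message: str | None = None):
        self.covariate = covariate
        super().__init__(message or f"separation detected for covariate {covariate!r}")
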