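"""Exception hierarchy for pbsource."""


class PbSourceError(ValueError):
    """Base class for all pbsource validation and solver errors."""


class FingerprintError(PbSourceError):
    """An isotope ratio or abundance value is invalid (non-positive, non-finite,
    or inconsistent with the closure constraint)."""


class UnidentifiableError(PbSourceError):
    """The mixing system cannot determine the source fractions uniquely,
    either because there are too many sources for the available equations
    or because the system matrix is singular."""


class DegenerateSourceError(PbSourceError):
    """Two or more end-member fingerprints coincide (or are collinear), so the
    design matrix is rank deficient."""


class TableFormatError(PbSourceError):
    """A sample table file violates the expected schema."""


class IllConditionedWarning(UserWarning):
    """The design matrix is numerically ill-conditioned; fractions are
    returned but may be unstable against measurement error."""
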