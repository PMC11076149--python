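"""Exception hierarchy for patient-input validation and model degeneracy."""


class NeovaxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NeovaxError):
    """A required column is missing or malformed in an input table."""


class ReferentialIntegrityError(NeovaxError):
    """A row references a gene/allele/variant/peptide key that does not resolve."""

    def __init__(self, message: str, offenders=()):
        super().__init__(message)
        self.offenders = tuple(offenders)


class DuplicateScoreError(NeovaxError):
    """The score table carries more than one row for a (variant, peptide, allele)."""


class DegenerateModelError(NeovaxError):
    """The model collapses: e.g. no pMHC complex is presented anywhere, or an
    all-zero cleavage vector makes the multinomial undefined."""
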