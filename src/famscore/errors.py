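"""Exception hierarchy for the famscore pipeline."""


class FamscoreError(Exception):
    """Base class for all famscore errors."""


class ParseError(FamscoreError):
    """A PED/MAP or TSV file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


class ValidationError(FamscoreError):
    """Input violated a structural invariant (duplicate IDs, bad columns, ...)."""


class DegenerateInputError(FamscoreError):
    """Analysis input carries no information (single class, constant predictor, empty)."""


class SeparationError(FamscoreError):
    """Complete separation: all informative within-pair differences share one sign."""


class ConvergenceError(FamscoreError):
    """An iterative fit failed to converge within its iteration budget."""


class MendelianInconsistencyError(FamscoreError):
    """A trio genotype configuration is impossible under Mendelian transmission."""


class RunawayRejectionError(FamscoreError):
    """Ascertainment acceptance probability too low to simulate the requested families."""
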