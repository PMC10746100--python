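"""Exception hierarchy for the pipeline."""


class MethyldietError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MethyldietError, ValueError):
    """A configuration value violates one of its documented invariants."""


class InputError(MethyldietError, ValueError):
    """Input data violate a precondition (shape, arm size, ids, ...)."""


class ParseError(MethyldietError, ValueError):
    """A delimited-text file could not be parsed; the message carries the location."""


class CollinearityError(MethyldietError, ValueError):
    """Exactly collinear predictor columns; the message names the offenders."""


class EmptyModelError(MethyldietError, ValueError):
    """Every predictor was pruned (or none was ever selected) for a diet arm."""


class MissingProbeError(MethyldietError, KeyError):
    """A weighted probe is absent from a methylation profile (strict policy)."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(f"missing probes: {', '.join(self.missing_ids)}")

    def __str__(self):  # KeyError quotes its payload by default
        return f"missing probes: {', '.join(self.missing_ids)}"


class DegenerateFitError(MethyldietError, ValueError):
    """The fitted model cannot support the requested inference (zero SE, ...)."""
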