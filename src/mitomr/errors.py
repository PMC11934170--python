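"""Exception hierarchy shared across the pipeline."""


class MitomrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MitomrError, ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(MitomrError, ValueError):
    """Records violate a domain invariant (bad alleles, se <= 0, ...)."""


class ConfigurationError(MitomrError, ValueError):
    """Inputs are internally inconsistent (e.g. missing LD positions)."""


class InsufficientInstrumentsError(MitomrError, ValueError):
    """An estimator was called with fewer instruments than it requires."""


class MergeError(MitomrError, ValueError):
    """Expression matrices cannot be merged (empty gene intersection)."""


class ScoringError(MitomrError, ValueError):
    """A gene set cannot be scored against the expression matrix."""
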