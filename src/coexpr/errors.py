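"""Exception hierarchy shared across the package."""


class CoexprError(Exception):
    """Base class for all package-specific errors."""


class DictionaryError(CoexprError):
    """A regex dictionary failed to load (bad pattern, duplicate label, wrong shape)."""


class ParameterError(CoexprError):
    """An operation received an out-of-range or inconsistent parameter."""


class NormalizationError(CoexprError):
    """Size-factor or dispersion estimation could not proceed on this input."""


class StoreError(CoexprError):
    """Correlation store lookup/build failure (unknown gene, missing group, bad layout)."""


class GmtError(CoexprError):
    """A GMT gene-set file is malformed."""


class AnalysisError(CoexprError):
    """An analysis mode's preconditions are not met by the input."""


class SimulationError(CoexprError):
    """A simulation spec is invalid."""
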