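"""Exception hierarchy shared across the pipeline."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """Malformed input table or configuration (e.g. a missing mandatory column)."""


class EmptyInputError(MRMediateError):
    """An input that must be non-empty contained zero usable records."""


class ParameterError(MRMediateError, ValueError):
    """A parameter value outside its valid domain."""


class MethodError(MRMediateError):
    """An estimator applied to data that cannot support it (e.g. too few variants)."""


class EmptyIntersectionError(MRMediateError):
    """Exposure and outcome share no variant ids at all."""


class CollinearExposuresError(MRMediateError):
    """Multivariable regression attempted on (near-)collinear exposure effects."""
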