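"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration value violates its contract (non-PSD correlation
    matrix, negative SD, malformed simplex, ...)."""


class InsufficientDataError(ValueError):
    """An estimator was asked to run on too little data (empty confusion
    cell, fewer trials than the fitting minimum, ...)."""


class CriterionUndefinedError(ValueError):
    """The set-size calibration criterion cannot be applied because the
    capacity estimate it keys on is undefined."""


class FitError(RuntimeError):
    """A model fit is structurally impossible (all choices at one boundary,
    rank-deficient design, ...)."""


class ParseError(ValueError):
    """A cohort file on disk does not match the expected schema."""
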