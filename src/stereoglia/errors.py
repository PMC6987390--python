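"""Package exceptions."""


class ParameterError(ValueError):
    """A configuration or probe parameter is outside its valid range."""


class EstimateError(RuntimeError):
    """An estimator cannot produce a defined value (e.g. zero sampled area)."""
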