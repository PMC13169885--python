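"""Shared exception types."""


class UndefinedFeatureError(ValueError):
    """A feature is undefined for this subject (e.g. zero word count or
    zero duration).  The subject should be flagged, not silently dropped."""


class InputError(ValueError):
    """Malformed input data (non-finite samples, bad p-values, ...)."""
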