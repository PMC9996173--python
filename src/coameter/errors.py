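"""Exception types shared across the pipeline."""


class CoameterError(Exception):
    """Base class for all package-specific failures."""


class NoLumenFound(CoameterError):
    """Segmentation produced an empty (or all-subthreshold) mask."""


class NoDiameterFound(CoameterError):
    """No diameter candidate survived the slope-matching search.

    The caller may relax the slope tolerance and retry; a zero diameter is
    never returned silently.
    """


class SchemaError(CoameterError):
    """A table or config file violates the expected schema."""


class UndefinedMetricError(CoameterError):
    """A metric's denominator is zero (degenerate confusion matrix)."""
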