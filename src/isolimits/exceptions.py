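"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration (bad fractions, unknown window, odd cell count...)."""


class EventNotApplicable(ValueError):
    """The requested alternative-splicing event cannot be applied to this isoform.

    Raised e.g. when exon skipping is requested for an isoform without an
    internal exon; callers are expected to resample another event type.
    """


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage label."""
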