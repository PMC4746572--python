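"""Exception types shared across the pipeline."""


class PrecisionIFError(Exception):
    """Base class for package-specific failures."""


class UnscorableCaseError(PrecisionIFError):
    """A case cannot produce a score (too few tiles, degenerate histogram, ...).

    Carries a machine-readable ``reason`` so the pipeline can record an
    explicit exclusion status instead of silently dropping the case.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)


class PipelineError(PrecisionIFError):
    """Cohort-level configuration problem (e.g. a batch missing its controls)."""
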