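"""Exception hierarchy shared across the package."""


class SmartScanError(Exception):
    """Base class for all smartscan errors."""


class ValidationError(SmartScanError, ValueError):
    """An input value violates a documented precondition."""


class UnreachableQualityError(SmartScanError, ValueError):
    """The requested quality standard lies outside the curve's range."""

    def __init__(self, quality_standard: float, q0: float, q1: float):
        self.quality_standard = quality_standard
        self.q0 = q0
        self.q1 = q1
        super().__init__(
            f"unreachable quality standard {quality_standard!r}: the quality "
            f"curve spans q(0)={q0!r} to q(1)={q1!r}"
        )
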