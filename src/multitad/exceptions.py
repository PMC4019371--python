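"""Exception types raised across the package."""


class MatrixFormatError(ValueError):
    """A contact-matrix file does not conform to the expected text layout."""


class BedFormatError(ValueError):
    """A BED file line cannot be parsed."""


class DomainValidationError(ValueError):
    """Intervals violate domain-set invariants (ordering, overlap, a < b)."""


class SpanTooLargeError(ValueError):
    """Interval span exceeds the largest span with enough diagonal windows
    to estimate the background mean; such domains are forbidden."""


class UndefinedScoreError(ValueError):
    """A statistic has no defined value for the given input (e.g. no
    qualifying domain pairs, or an empty interval collection)."""


class InfeasiblePackingError(ValueError):
    """Requested random domains cannot be packed into the chromosome."""
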