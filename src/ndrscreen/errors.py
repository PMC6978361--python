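"""Exception hierarchy shared across the package."""


class NdrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NdrError):
    """Invalid configuration: unknown metric, missing column mapping, bad layout."""


class ParseError(NdrError):
    """A raw input row could not be parsed; the message names the row."""


class ValidationError(NdrError):
    """A well or table violates a structural invariant (duplicate well, bad role...)."""


class MetricError(NdrError):
    """A response metric is undefined for the given inputs.

    Raised for zero start readouts (undefined fold change), non-growing
    negative controls (fold change 1), positive controls with fold change 1,
    and degenerate endpoint controls (equal negative/positive medians).
    """


class ControlError(NdrError):
    """A plate lacks the control wells needed for normalization or QC."""


class FitError(NdrError):
    """Dose-response fitting cannot proceed (too few points, length mismatch)."""
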