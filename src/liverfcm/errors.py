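"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`InputError` and
:class:`ConfigError` -> 2, degenerate-computation errors -> 3.
"""


class LiverFCMError(Exception):
    """Base class for all package errors."""


class InputError(LiverFCMError):
    """Invalid or inconsistent user input (shapes, lengths, ranges, files)."""


class ConfigError(LiverFCMError):
    """Invalid configuration value (e.g. non-positive calibration slope)."""


class DegenerateFeatureError(LiverFCMError):
    """A clustering feature is constant over the ROI and cannot be normalized."""


class DegenerateClusteringError(LiverFCMError):
    """Clustering collapsed (identical centroids); clusters cannot be told apart."""


class NoiseEstimationError(LiverFCMError):
    """Noise standard deviation could not be estimated (zero or undefined)."""
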