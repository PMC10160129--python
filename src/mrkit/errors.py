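"""Exception hierarchy for mrkit.

Every error raised on purpose by the package derives from :class:`MRKitError`
so callers (notably the study pipeline, which must keep going when one
outcome fails) can catch a single base class.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A run configuration or column mapping is invalid."""


class InputError(MRKitError):
    """An input file is unreadable, empty, or structurally broken."""


class EmptyInstrumentError(MRKitError):
    """No SNP passed the genome-wide significance threshold for a trait."""


class EmptyHarmonizationError(MRKitError):
    """No SNP survived exposure/outcome harmonization."""


class DegenerateInstrumentError(MRKitError):
    """An instrument has a zero exposure effect, so its Wald ratio is undefined."""


class EmptySetError(MRKitError):
    """An estimator was called on an empty instrument set."""


class InsufficientInstrumentsError(MRKitError):
    """Fewer instruments than the estimator's minimum."""


class CollinearityError(MRKitError):
    """Design matrix is (numerically) rank deficient."""


class DegenerateCorrectionError(MRKitError):
    """Outlier removal flagged every instrument."""


class NotEstimableError(MRKitError):
    """A derived quantity (e.g. proportion mediated with zero total effect)
    is undefined for the given inputs."""
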