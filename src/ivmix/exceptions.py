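"""Package exception hierarchy."""


class IvmixError(Exception):
    """Base class for all ivmix errors."""


class SummaryDataError(IvmixError):
    """Malformed or invalid summary-statistic input."""


class DegenerateInstrumentError(IvmixError):
    """A variant's exposure association is exactly zero, so no ratio exists."""


class EmptyDatasetError(IvmixError):
    """No usable variants remain after filtering."""


class EmptyClusterError(IvmixError):
    """A substantive cluster received numerically zero total responsibility."""


class UnderflowError(IvmixError):
    """All component densities underflowed to zero for some observation."""
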