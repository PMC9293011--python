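"""Exception hierarchy.

Every error raised by the library derives from :class:`AdmixDateError` so
callers (and the CLI) can distinguish domain errors from programming bugs.
"""


class AdmixDateError(Exception):
    """Base class for all admixdate errors."""


class EigenstratParseError(AdmixDateError):
    """Malformed EIGENSTRAT input; message names the file and offending row."""


class InvariantError(AdmixDateError):
    """A domain-type invariant was violated (e.g. a het call in pseudo-haploid data)."""


class LookupError_(AdmixDateError):
    """An individual or group label did not resolve."""


class EstimationError(AdmixDateError):
    """Mixture-proportion regression could not be performed."""


class FitError(AdmixDateError):
    """Exponential fit failed (e.g. no populated bins in the fit range)."""


class JackknifeError(AdmixDateError):
    """Too few usable leave-one-out blocks."""


class SimulationError(AdmixDateError):
    """Simulator contract violation (parameter range, pool exhaustion)."""
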