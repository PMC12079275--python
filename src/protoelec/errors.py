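"""Exception hierarchy shared across the package.

All errors derive from :class:`ProtoelecError` so callers can catch the
package's failures with one clause; each subclass maps to one failure
class the pipeline distinguishes (bad spec, bad file, bad maths input,
non-convergence, numerical blow-up, not enough data).
"""


class ProtoelecError(Exception):
    """Base class for all protoelec errors."""


class InvalidSpecError(ProtoelecError, ValueError):
    """A generator/circuit specification violates its invariants."""


class DomainError(ProtoelecError, ValueError):
    """A numeric argument is outside the mathematical domain of a formula."""


class FormatError(ProtoelecError, ValueError):
    """A file does not conform to the expected CSV/config layout."""


class ConvergenceError(ProtoelecError, RuntimeError):
    """An iterative fit failed to converge."""


class InsufficientDataError(ProtoelecError, ValueError):
    """Too few samples/points for the requested analysis."""


class InstabilityError(ProtoelecError, RuntimeError):
    """A simulation produced non-finite fields."""


class NoPeakError(ProtoelecError, ValueError):
    """No confident spectral peak found (flat or noise-dominated series)."""
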