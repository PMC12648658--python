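"""Exception hierarchy.

Everything raised deliberately by solvkit derives from :class:`SolvkitError`
so the CLI can catch one type and print a one-line diagnostic.
"""


class SolvkitError(Exception):
    """Base class for all solvkit errors."""


class ParseError(SolvkitError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(SolvkitError, ValueError):
    """Inputs violate a documented precondition or invariant."""


class DegenerateFitError(SolvkitError):
    """The fitting objective is flat in a free parameter."""


class PackingError(SolvkitError):
    """A random-geometry generator could not satisfy distance constraints."""


class StabilityError(SolvkitError):
    """Integrator parameters outside the stable regime."""
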