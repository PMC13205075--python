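"""Exception hierarchy for the package.

All validation failures raise one of these so callers can distinguish a
malformed input file (FormatError), inputs that disagree with each other
(ConsistencyError), and a simulation that cannot satisfy its constraints
(SimulationError).
"""


class CernaScreenError(Exception):
    """Base class for all package errors."""


class FormatError(CernaScreenError, ValueError):
    """A file or value violates the expected format or a type invariant."""


class ConsistencyError(CernaScreenError, ValueError):
    """Two inputs that must agree (e.g. counts header vs. metadata) do not."""


class SimulationError(CernaScreenError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""
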