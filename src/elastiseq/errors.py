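"""Exception hierarchy shared across the package.

``ValidationError`` covers anything a pipeline's pre-processing phase should
catch (bad input files, bad configuration); ``CapacityError`` is the simulated
provider refusing an instance request; ``SimulationError`` signals an internal
inconsistency of the event simulation (e.g. jobs that can never be scheduled).
"""


class ElastiseqError(Exception):
    """Base class for all package errors."""


class ValidationError(ElastiseqError):
    """Invalid input data or configuration (fails a pipeline in phase 1)."""


class CapacityError(ElastiseqError):
    """The cloud provider refused an instance request (cap exceeded)."""


class SimulationError(ElastiseqError):
    """The discrete-event simulation reached an inconsistent state."""
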