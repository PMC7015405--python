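"""Exception hierarchy for netdist."""


class NetdistError(Exception):
    """Base class for all netdist errors."""


class GraphValidationError(NetdistError):
    """A graph or graph file violates a structural invariant."""


class DisconnectedGraphError(NetdistError):
    """An operation that requires a connected graph received a disconnected one."""


class SizeMismatchError(NetdistError):
    """A node-correspondence distance received graphs of different sizes."""


class SamplingError(NetdistError):
    """A random-graph sampler could not satisfy its constraints."""


class DegenerateStatisticError(NetdistError):
    """A statistic is undefined for the given inputs (e.g. zero null variance)."""
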