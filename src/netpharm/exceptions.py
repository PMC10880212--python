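"""Exception hierarchy shared across the package."""


class NetpharmError(Exception):
    """Base class for all package errors."""


class FormatError(NetpharmError):
    """Malformed input file (bad header, wrong column count, cyclic ontology)."""


class EmptyNetworkError(NetpharmError):
    """A network operation produced or received a graph with no usable content."""


class EmptySubnetworkError(NetpharmError):
    """Induced subnetwork has no nodes."""


class ConnectivityError(NetpharmError):
    """Operation requires a connected graph but got a disconnected one."""


class InsufficientDataError(NetpharmError):
    """Not enough observations for the requested estimate."""


class ParameterError(NetpharmError):
    """A tuning parameter is outside its documented range."""


class NoSignalError(NetpharmError):
    """Reference gene list does not intersect the analysis universe."""
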