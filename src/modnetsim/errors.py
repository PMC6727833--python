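"""Exception hierarchy.

All data-level failures derive from :class:`ModnetError` so the CLI can map
them to a single non-zero exit code distinct from usage errors.
"""


class ModnetError(Exception):
    """Base class for all package-level errors."""


class ConfigError(ModnetError):
    """Invalid configuration value or combination."""


class SchemaError(ModnetError):
    """Malformed on-disk network file."""


class SelfLoopError(SchemaError):
    """Edge list row with identical endpoints."""


class DuplicateEdgeError(SchemaError):
    """The same unordered node pair appears more than once."""


class UnknownNodeError(SchemaError):
    """Edge references a node absent from the node table."""


class MissingMembershipError(SchemaError):
    """A node row lacks a module assignment."""


class MissingAbundanceError(ModnetError):
    """Abundance-based sampling requested on a network without abundances."""


class DegenerateGraphError(ModnetError):
    """Graph cannot support the requested operation (e.g. zero total degree)."""


class DegenerateDataError(ModnetError):
    """Statistical procedure undefined on the supplied data."""
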