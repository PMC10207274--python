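"""Exception hierarchy.

All package-specific errors derive from :class:`MicropkaError` so callers
(and the CLI) can map failure classes to distinct exit codes.
"""


class MicropkaError(Exception):
    """Base class for every error raised by this package."""


class SchemaError(MicropkaError, ValueError):
    """Malformed input: bad occupancy vectors, bad JSON/CSV system files,
    ambiguous representations (e.g. both 'energies' and 'edges' present)."""


class SizeError(MicropkaError, ValueError):
    """A requested problem size is out of the supported range
    (site counts outside 1..20, empty pH grids, ...)."""


class ConsistencyError(MicropkaError):
    """A microconstant set violates thermodynamic cycle closure, or a
    system fails a structural/internal consistency check in strict mode."""


class WindowError(MicropkaError):
    """A root search (pK50 midpoint) found no bracket inside the scan
    window; the caller should widen the window."""
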