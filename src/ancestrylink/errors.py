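"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`FormatError`, :class:`IdError`
and :class:`ParamError` are usage/input problems (exit 2); the remaining
domain errors (labelling, consistency) map to exit 1.
"""


class AncestryLinkError(Exception):
    """Base class for all package errors."""


class FormatError(AncestryLinkError):
    """A text table could not be parsed (missing column, bad cell, ...)."""


class IdError(AncestryLinkError):
    """A node id does not exist, or sample/ancestor sets are ill-formed."""


class ParamError(AncestryLinkError):
    """Invalid simulation or query parameters."""


class LabelError(AncestryLinkError):
    """An ancestor node has no population label (population == -1)."""


class ConsistencyError(AncestryLinkError):
    """Rows violate an internal invariant (e.g. overlapping tracts)."""


class DataError(AncestryLinkError):
    """Structurally impossible genealogy (e.g. a cycle in parent pointers)."""
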