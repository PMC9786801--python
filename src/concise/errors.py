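"""Exception hierarchy.

All tool errors derive from :class:`ConciseError` so the CLI can catch one
type, print a named error class and exit non-zero without a traceback.
"""


class ConciseError(Exception):
    """Base class for all errors raised by this package."""


class InputError(ConciseError):
    """A caller-supplied value is invalid (bad id, empty key, bad spec)."""


class SchemaError(ConciseError):
    """An input table is missing required columns or violates its contract."""


class TransportError(ConciseError):
    """An HTTP fetch failed; carries the status/reason in the message."""


class ConsistencyError(ConciseError):
    """Cross-input invariants violated (e.g. results for unknown components)."""
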