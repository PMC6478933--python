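"""Exception hierarchy shared across the package."""


class PoreclogError(Exception):
    """Base class for all poreclog errors."""


class FormatError(PoreclogError, ValueError):
    """Malformed or inconsistent input files (e.g. atom-count mismatch)."""


class ValidationError(PoreclogError, ValueError):
    """Invalid arguments or data violating a documented contract."""


class LookupTableError(PoreclogError, KeyError):
    """A required entry is missing from a lookup table (no silent default)."""


class DegenerateInputError(PoreclogError, ValueError):
    """Mathematically degenerate input: zero bulk occupancy, constant x in a
    regression, zero reference current, and the like."""


class PlacementError(PoreclogError, RuntimeError):
    """Synthetic particle placement failed after bounded retries."""
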