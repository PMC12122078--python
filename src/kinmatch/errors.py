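"""Exception hierarchy for kinmatch.

All fatal, user-facing conditions raise :class:`KinmatchError` (or a
subclass) so the CLI can map them to a stable exit code. Anything else
escaping the library is a genuine bug.
"""


class KinmatchError(Exception):
    """Base class for all anticipated kinmatch failures."""


class ValidationError(KinmatchError):
    """An input file or in-memory object violates a documented invariant."""
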