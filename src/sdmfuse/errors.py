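"""Error type shared across the package.

Every anticipated failure raises :class:`SDMFuseError` carrying a short
machine-readable ``code`` (e.g. ``"empty-domain"``, ``"schema-error"``) so
callers and tests can branch on the failure mode without parsing messages.
"""

from __future__ import annotations


class SDMFuseError(ValueError):
    """Domain error with a stable short code."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)
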