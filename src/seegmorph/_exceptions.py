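"""Exception hierarchy for seegmorph.

All package-specific failures derive from :class:`SeegMorphError` so callers
(and the CLI) can catch one base class. Plain ``ValueError`` is reserved for
domain errors on scalar arguments (e.g. a morph parameter outside [0, 1]).
"""


class SeegMorphError(Exception):
    """Base class for all seegmorph errors."""


class FormatError(SeegMorphError):
    """A file is not in a supported format (e.g. wrong magic bytes)."""


class CorruptFileError(SeegMorphError):
    """A file has the right format signature but a truncated/garbled payload."""


class ValidationError(SeegMorphError):
    """An in-memory object violates its invariants (bad names, NaNs, ...)."""


class CorrespondenceError(SeegMorphError):
    """A folded/inflated surface pair does not share vertex identity."""


class InconsistencyError(SeegMorphError):
    """Two objects that must describe the same surface disagree (lengths,
    stale vertex indices, ...)."""
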