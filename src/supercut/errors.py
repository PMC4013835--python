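"""Exception hierarchy shared across the package."""


class SupercutError(Exception):
    """Base class for all package errors."""


class NewickParseError(SupercutError):
    """Malformed Newick input."""


class ValidationError(SupercutError):
    """An object violates a structural invariant (duplicate labels, degree-2
    vertices, overlapping internal-vertex id spaces, ...)."""


class DomainError(SupercutError):
    """An operation was called outside its stated precondition."""


class IncompatibleSplitsError(SupercutError):
    """Raised by tree construction when two splits cannot coexist in a tree.

    Carries the offending pair in :attr:`pair`.
    """

    def __init__(self, s1, s2):
        self.pair = (s1, s2)
        super().__init__(f"incompatible splits: {s1} vs {s2}")


class ResourceExhaustedError(SupercutError):
    """A size guard or work budget was exceeded; the answer is *unknown*,
    not *no*."""


class InternalConsistencyError(SupercutError):
    """A verified theorem-backed post-condition failed; indicates a bug
    upstream, never a property of the input."""


class FixtureError(SupercutError):
    """A worked-example fixture failed its self-verification against the
    printed cuts/splits; the transcription must be re-checked."""
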