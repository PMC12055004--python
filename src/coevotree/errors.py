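"""Exception hierarchy for coevotree.

Every error raised by the library derives from :class:`CoevotreeError` so
callers can catch package failures with a single handler while still
distinguishing the specific failure mode.
"""


class CoevotreeError(Exception):
    """Base class for all coevotree errors."""


class InvalidParameterError(CoevotreeError, ValueError):
    """A simulation or analysis parameter violates its domain."""


class InvalidAlignmentError(CoevotreeError, ValueError):
    """An alignment violates its invariants (ragged rows, duplicate taxa...)."""


class InvalidTreeError(CoevotreeError, ValueError):
    """A tree violates its invariants (non-finite branch lengths...)."""


class NewickParseError(CoevotreeError, ValueError):
    """Malformed Newick input; carries a best-effort position message."""


class MissingBranchLengthError(CoevotreeError, ValueError):
    """A branch length required for patristic distances is absent.

    ``branch`` names the child end of the offending branch (a tip label or a
    description of the internal node).
    """

    def __init__(self, branch: str):
        self.branch = branch
        super().__init__(f"branch above {branch!r} has no length; "
                         "patristic distances are uncomputable")


class UncomputableDistanceError(CoevotreeError):
    """No comparable (both ungapped) sites remain for a sequence pair."""

    def __init__(self, taxon_a: str, taxon_b: str):
        self.pair = (taxon_a, taxon_b)
        super().__init__(
            f"no comparable sites between {taxon_a!r} and {taxon_b!r} "
            "after pairwise gap deletion")


class InsufficientOverlapError(CoevotreeError, ValueError):
    """Fewer than the minimum common taxa shared by two distance matrices."""


class UndefinedCorrelationError(CoevotreeError, ValueError):
    """Pearson correlation undefined: zero variance in a distance vector."""


class DegenerateSampleSizeError(CoevotreeError, ValueError):
    """Fisher z variance 1/(N-3) is undefined or non-positive (N < 4)."""
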