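"""Exception hierarchy for strucphylo."""


class StrucPhyloError(Exception):
    """Base class for all strucphylo errors."""


class FormatError(StrucPhyloError):
    """A structure or tree file could not be parsed."""


class AmbiguityError(StrucPhyloError):
    """The requested record is ambiguous (e.g. multiple chains, no chain given)."""


class EmptyModelError(StrucPhyloError):
    """A structure model contains no usable residues."""


class QCError(StrucPhyloError):
    """A quality-control precondition was violated."""


class AlignmentError(StrucPhyloError):
    """Pairwise or progressive structural alignment failed."""


class TreeError(StrucPhyloError):
    """Tree construction, rooting or comparison failed."""


class DominanceError(StrucPhyloError):
    """A similarity matrix violates self-score dominance (negative distance)."""


class SamplingError(StrucPhyloError):
    """Jackknife column sampling could not satisfy its constraints."""
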