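"""Exception types raised across the package."""


class VaratreeError(Exception):
    """Base class for all package-specific errors."""


class EmptyReferenceError(VaratreeError):
    """The FASTA input contained no sequences."""


class DuplicateSequenceError(VaratreeError):
    """Two FASTA records share the same name."""


class UnknownChromosomeError(VaratreeError, KeyError):
    """A query named a chromosome absent from the reference."""


class InvalidVariantError(VaratreeError, ValueError):
    """A variant record violates its type invariants."""


class EmptyWindowError(VaratreeError, ValueError):
    """A zero-length extension window was passed to tree construction."""


class UnknownPathError(VaratreeError, KeyError):
    """A path id does not exist in the variation tree."""


class PathExplosionError(VaratreeError):
    """Path enumeration exceeded the configured cap.

    Lower ``max_variants_per_path`` or rely on the pruning heuristic in the
    extension stage.
    """


class CigarCompositionError(VaratreeError, ValueError):
    """ALT-coordinate CIGAR is inconsistent with the path haplotype."""


class IndexFormatError(VaratreeError):
    """On-disk index is missing or has an unsupported format version."""
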