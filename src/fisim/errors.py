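"""Exception hierarchy for the fisim toolkit."""


class FisimError(Exception):
    """Base class for all toolkit-specific errors."""


class FastaError(FisimError):
    """Malformed or unusable FASTA input."""


class EmptyInputError(FastaError):
    """The input file contains no sequence records."""


class DuplicateIdError(FastaError):
    """Two records in one dataset share an identifier."""


class ShortSequenceError(FastaError):
    """A record has fewer than two usable (A/C/G/T) residues."""


class PhylipFormatError(FisimError):
    """Malformed PHYLIP distance-matrix file or unserialisable matrix."""


class PhylipNameError(PhylipFormatError):
    """Taxon names collide after truncation to the PHYLIP name width."""
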