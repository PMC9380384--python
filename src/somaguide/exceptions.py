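"""Exception hierarchy for somaguide."""


class SomaguideError(Exception):
    """Base class for all package-specific errors."""


class DuplicateContigError(SomaguideError):
    """Two FASTA records share a contig name."""


class VcfFormatError(SomaguideError):
    """A VCF body line is structurally malformed."""


class RefMismatchError(SomaguideError):
    """A variant's REF allele does not match the supplied genome."""


class UnknownContigError(SomaguideError):
    """A variant references a contig absent from the genome."""
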