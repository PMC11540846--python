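"""Exception hierarchy.

FormatError covers malformed input files (bad SEG/VCF/cycles grammar);
DataError covers inputs that parse but are scientifically inconsistent
(overlapping segments, VAF implying more mutant copies than exist).
The CLI maps these onto distinct exit codes.
"""


class EcdnaKitError(Exception):
    """Base class for all ecdnakit errors."""


class FormatError(EcdnaKitError):
    """A file does not conform to its documented grammar."""


class DataError(EcdnaKitError):
    """Input parsed but is internally inconsistent or out of domain."""


class UndefinedResultError(DataError):
    """A quantity is mathematically undefined for the given input."""


class UnattributableMutationError(DataError):
    """No signature assigns positive likelihood to a mutation's channel."""
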