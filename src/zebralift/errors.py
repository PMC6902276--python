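"""Exception hierarchy.

``FormatError`` covers malformed external files, ``ValidationError`` covers
inputs that parse but are inconsistent with each other (e.g. a VCF REF allele
disagreeing with the genome), and ``ContractError`` covers violated call
preconditions. All derive from ``ZebraliftError`` so callers can catch broadly.
"""


class ZebraliftError(Exception):
    pass


class FormatError(ZebraliftError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ZebraliftError, ValueError):
    """Parsed inputs are mutually inconsistent."""


class ContractError(ZebraliftError, ValueError):
    """A function precondition was violated."""
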