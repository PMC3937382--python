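"""Exception hierarchy shared across the package.

``ValidationError`` marks bad user input (malformed files, illegal residues,
inconsistent tables); everything else derives from ``KinscanError`` so the
CLI can map validation problems to exit code 2 and internal failures to 1.
"""


class KinscanError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KinscanError, ValueError):
    """Invalid input data or configuration."""


class ParseError(ValidationError):
    """A text input (FASTA, motif pattern, newick, profile file) failed to parse."""


class DegenerateAlignmentError(ValidationError):
    """An alignment became empty or unusable (e.g. all columns trimmed)."""


class UnanchorableError(KinscanError):
    """A sequence scored below the profile cutoff and cannot be subdomain-anchored."""
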