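"""Exception hierarchy shared across the package."""


class FragGrowError(Exception):
    """Base class for all package errors."""


class FormatError(FragGrowError):
    """A file could not be parsed in the named format."""


class ChemistryError(FragGrowError):
    """A molecule violates valence or element constraints."""


class ConfigError(FragGrowError):
    """Invalid configuration (bad SMARTS rule, empty scaffold, bad scales)."""


class LibraryIntegrityError(FragGrowError):
    """A side-chain library violates its invariants (cardinality, heteroatoms,
    duplicate canonical forms, multiple attachment points)."""


class SelectionError(FragGrowError):
    """A receptor/ligand selector matched zero or more than one group."""


class GeometryError(FragGrowError):
    """Impossible fixture or pocket geometry."""


class MinimizationError(FragGrowError):
    """Energy minimization diverged (NaN energy)."""


class ConformerError(FragGrowError):
    """Conformer embedding failed for a compound."""


class NoPoseError(FragGrowError):
    """No valid pose exists (compound larger than the scoring box)."""


class InputError(FragGrowError):
    """Malformed tabular input (NaN scores, duplicate or missing rows,
    inconsistent libraries across rank tables)."""


class FixtureIntegrityError(FragGrowError):
    """A shipped fixture file does not match its checksum manifest."""
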