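"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class FenmorError(Exception):
    """Base class for all package errors."""


class ConfigError(FenmorError):
    """Invalid configuration or parameters."""


class DataError(FenmorError):
    """Invalid, inconsistent or unreadable input data."""


class StructureError(DataError):
    """Topology/trajectory problems (mismatched atom counts, bad PDB...)."""


class SelectionError(DataError):
    """A required atom selection resolved to nothing or references
    nonexistent atoms/residues."""
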