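"""Exception hierarchy for the synergyscreen pipeline."""


class SynergyScreenError(Exception):
    """Base class for all synergyscreen errors."""


class ConfigError(SynergyScreenError):
    """Invalid configuration value."""


class DataError(SynergyScreenError):
    """Malformed or missing input data."""


class ChemistryError(SynergyScreenError):
    """A SMILES string could not be handled by the structure layer."""

    def __init__(self, message: str, smiles=None):
        super().__init__(message)
        self.smiles = smiles


class MembershipError(SynergyScreenError):
    """A compound cannot be attributed to any herb of a prescription."""


class ParseError(DataError):
    """A structured text input failed to parse; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class InsufficientDataError(SynergyScreenError):
    """Too few observations for the requested statistical comparison."""
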