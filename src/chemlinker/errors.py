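"""Exception hierarchy shared across the engine."""


class ChemLinkerError(Exception):
    """Base class for all engine errors."""


class InvalidInputError(ChemLinkerError, ValueError):
    """A function argument violates its contract (bad threshold, length mismatch...)."""


class StoreError(ChemLinkerError):
    """The data store is missing, malformed, or referentially broken."""


class QueryError(ChemLinkerError):
    """A query cannot be processed (empty or unfingerprintable SMILES)."""


class GenerationError(ChemLinkerError):
    """A fixture specification cannot be satisfied (e.g. infeasible target similarity)."""
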