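"""Exception hierarchy for npcquant.

All package errors derive from :class:`NpcQuantError` so callers can catch
one base class at pipeline boundaries.
"""


class NpcQuantError(Exception):
    """Base class for all npcquant errors."""


class ValidationError(NpcQuantError, ValueError):
    """Structurally invalid input (missing fields, bad shapes, bad config)."""


class DomainError(NpcQuantError, ValueError):
    """Numerically out-of-domain input (e.g. non-positive normalizer)."""


class SmilesParseError(NpcQuantError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class VinaParseError(NpcQuantError, ValueError):
    """Docking-engine output could not be parsed."""


class DegenerateFieldError(NpcQuantError, ValueError):
    """An image field has no pixel above the low threshold; the ratio is undefined."""


class UndefinedCorrelationError(NpcQuantError, ValueError):
    """Pearson correlation undefined (constant channel in scope)."""


class DegenerateDataError(NpcQuantError, ValueError):
    """Group data degenerate for the requested statistical test."""


class GenerationError(NpcQuantError, ValueError):
    """A synthetic-data spec cannot be realized (e.g. infeasible packing)."""


class ConfigError(NpcQuantError, ValueError):
    """Pipeline configuration invalid."""


class StageError(NpcQuantError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")
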