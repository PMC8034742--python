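"""Exception hierarchy for the pipeline.

Every error that a stage can raise on bad input derives from
:class:`ForestRoutesError`, so callers (and the CLI) can distinguish
domain failures from programming errors.
"""


class ForestRoutesError(Exception):
    """Base class for all domain errors."""


class EmptyGeometryError(ForestRoutesError):
    """Geometry cleaning removed every part of a feature."""


class AntimeridianError(ForestRoutesError):
    """Input coordinates cross or exceed the +/-180 degree meridian."""


class MissingAttributeError(ForestRoutesError):
    """A required feature property (e.g. ``species``) is absent."""


class MissingColumnError(ForestRoutesError):
    """A required CSV column is absent."""


class DuplicateSpeciesError(ForestRoutesError):
    """A table that requires one row per species has duplicates."""


class UnknownEcoregionError(ForestRoutesError):
    """A corridor definition names ecoregions absent from the input.

    Carries the full list of unresolved names in ``names``.
    """

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(f"unknown ecoregions: {', '.join(self.names)}")


class NotForestAssociatedError(ForestRoutesError):
    """A species has no forest habitat record and fails the inclusion criterion."""


class MissingHabitatError(ForestRoutesError):
    """Species lack a habitat class when building the contingency table."""

    def __init__(self, species):
        self.species = sorted(species)
        super().__init__(f"no habitat class for: {', '.join(self.species)}")


class DegenerateTableError(ForestRoutesError):
    """Contingency table has fewer than two rows or columns after drops."""


class InfeasibleLayoutError(ForestRoutesError):
    """Synthetic world sizes cannot satisfy the requested clearances."""
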