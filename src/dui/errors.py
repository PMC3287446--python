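"""Exception hierarchy for the dui package."""


class DUIError(Exception):
    """Base class for all dui errors."""


class ValidationError(DUIError, ValueError):
    """Invalid input data or configuration."""


class DuplicateDatasetError(ValidationError):
    """The same dataset_id was registered twice."""


class UnknownUnitError(DUIError, KeyError):
    """An analysis unit is not present in the registry."""


class OrphanSpeciesError(DUIError):
    """A species profile references species absent from the baseline.

    Silently skipping orphans would change the profile size p and bias the
    crown indicator, so this is always a hard error.
    """

    def __init__(self, species: list[str]):
        self.species = sorted(species)
        super().__init__(
            "species in profile but not in baseline: " + ", ".join(self.species)
        )


class SnapshotMismatchError(DUIError):
    """Inputs changed under an existing snapshot label."""
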