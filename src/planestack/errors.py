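"""Exception hierarchy for planestack."""


class PlanestackError(Exception):
    """Base class for all planestack errors."""


class LayoutError(PlanestackError, ValueError):
    """A layout specification or directory layout is invalid."""


class ShapeError(PlanestackError):
    """Planes within one position disagree in shape or pixel type."""


class CompletenessError(PlanestackError):
    """The timepoint x channel x z grid has missing cells and the fill
    policy forbids fabricating planes."""

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing or [])


class DatasetConflictError(PlanestackError):
    """An image for the same position already exists in the dataset."""


class PluginError(PlanestackError):
    """A runtime plug-in could not be loaded or violates its contract."""
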