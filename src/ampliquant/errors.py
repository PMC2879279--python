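"""Exception hierarchy for ampliquant."""


class AmpliquantError(Exception):
    """Base class for all ampliquant errors."""


class PanelFormatError(AmpliquantError):
    """A panel file is structurally malformed (missing columns, bad types)."""


class PanelValidationError(AmpliquantError):
    """A panel violates an assay invariant (duplicate lengths, no references, ...)."""


class RegionNotFoundError(AmpliquantError, KeyError):
    """A region name does not resolve to any target amplicon in the panel."""


class PeakTableError(AmpliquantError):
    """A peak table or sample sheet row cannot be parsed."""


class ConfigurationError(AmpliquantError):
    """Invalid analysis configuration (no controls, impossible copy state, ...)."""
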