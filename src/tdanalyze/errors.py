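"""Exception hierarchy.

Every user-facing error derives from :class:`TdanalyzeError` so callers can
catch the package's failures with a single except clause.
"""


class TdanalyzeError(Exception):
    """Base class for all tdanalyze errors."""


class ParameterError(TdanalyzeError, ValueError):
    """A numeric parameter violates its documented bound."""


class TopologyError(TdanalyzeError, ValueError):
    """A residue/atom request is inconsistent with the molecular topology."""


class SelectionError(TdanalyzeError, ValueError):
    """An atom selection resolved to nothing (missing atom, chain or residue)."""


class ScheduleError(TdanalyzeError, ValueError):
    """Occupancy schedules conflict (e.g. two schedules move the same atom)."""


class AlignmentError(TdanalyzeError, ValueError):
    """Contact maps being merged do not share residue indexing."""


class ConfigError(TdanalyzeError, ValueError):
    """An analysis configuration is invalid."""


class InputError(TdanalyzeError, ValueError):
    """Input data is empty or otherwise unusable."""
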