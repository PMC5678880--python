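"""Exception hierarchy for the hyporules pipeline.

Each error class maps to a distinct process exit code in the CLI
(schema/value problems: 2, unresolvable staining scores: 3, bad
parameters: 4) so shell pipelines can branch on failure mode.
"""


class HyporulesError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class SchemaError(HyporulesError):
    """A required column or field is missing from an input table."""

    exit_code = 2


class CohortValueError(HyporulesError):
    """A cell holds a string outside its closed vocabulary."""

    exit_code = 2


class IntegrityError(HyporulesError):
    """A structural invariant is violated (e.g. duplicate tumor id)."""

    exit_code = 2


class UnresolvedScoreError(HyporulesError):
    """A medium-positivity score has neither an explicit resolution
    nor a staining intensity to dichotomize it with."""

    exit_code = 3


class ParameterError(HyporulesError):
    """An operation was called with an out-of-range parameter."""

    exit_code = 4


class InconsistencyError(HyporulesError):
    """No assignment of the medium cells reproduces the target counts."""

    exit_code = 2
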