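"""Exception hierarchy for fflhub.

All errors derive from :class:`FFLHubError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the pipeline stages (bad configuration, malformed
input tables, degenerate statistics, impossible graph/network requests).
"""


class FFLHubError(Exception):
    """Base class for all fflhub errors."""


class InvalidConfigError(FFLHubError, ValueError):
    """A simulation or run configuration violates its invariants."""


class InputMismatchError(FFLHubError, ValueError):
    """Expression matrix and phenotype table do not describe the same samples."""


class DegenerateVarianceError(FFLHubError, ValueError):
    """A statistical test is undefined because every observation is constant."""


class SchemaError(FFLHubError, ValueError):
    """A required column is missing from an input table."""


class ValidationError(FFLHubError, ValueError):
    """A value in an input table is outside its legal domain."""


class TypeConflictError(FFLHubError, ValueError):
    """The same identifier is used with two different node roles."""


class NoFFLError(FFLHubError, ValueError):
    """No feed-forward loop exists, so a top subnetwork cannot be chosen."""


class AlphabetError(FFLHubError, ValueError):
    """A nucleotide sequence contains residues outside {A, C, G, U/T}."""


class PipelineError(FFLHubError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
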