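"""Exception hierarchy shared by all phagechar modules."""


class PhagecharError(Exception):
    """Base class for errors raised by phagechar."""


class FastaParseError(PhagecharError, ValueError):
    """Malformed FASTA input."""


class AlphabetError(PhagecharError, ValueError):
    """Sequence contains characters outside the strict ACGT alphabet."""


class ConfigError(PhagecharError, ValueError):
    """Invalid or unknown configuration key/value."""


class SpecError(PhagecharError, ValueError):
    """Infeasible synthetic genome specification."""


class GenerationError(PhagecharError, RuntimeError):
    """Synthetic data generator could not satisfy its constraints."""


class PartitionError(PhagecharError, ValueError):
    """Too few ORFs to partition a genome into transcription regions."""


class FlatCurveError(PhagecharError, ValueError):
    """One-step growth curve shows no rise above the initial titer."""


class DegenerateFitError(PhagecharError, ValueError):
    """No breakpoint pair leaves at least two samples in every phase."""
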