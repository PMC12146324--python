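"""Exception hierarchy.

Every error raised by the package derives from :class:`LncsublocError`
so callers can catch the whole family with one clause.
"""


class LncsublocError(Exception):
    """Base class for all package errors."""


class FastaParseError(LncsublocError):
    """Malformed FASTA input; carries the offending line number when known."""


class EmptyDatasetError(LncsublocError):
    """An input that must contain at least one record was empty."""


class DuplicateIdError(LncsublocError):
    """Two records in one dataset share an identifier."""


class InvalidAlphabetError(LncsublocError):
    """A residue outside the A/C/G/T (or U) alphabet under the strict policy."""


class SequenceTooShortError(LncsublocError):
    """Sequence shorter than an encoder's minimum length; names the encoder."""


class StratificationError(LncsublocError):
    """A class has too few members for the requested stratified split or CV."""


class UndefinedMetricError(LncsublocError):
    """A metric that has no defined value for the given input (e.g. one-class AUC)."""


class UnknownClassifierError(LncsublocError):
    """A classifier name not present in the registry."""


class FeatureMismatchError(LncsublocError):
    """Feature names of the input do not match those a saved model was trained on."""


class ConfigError(LncsublocError):
    """Invalid configuration value."""
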