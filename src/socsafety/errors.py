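"""Exception hierarchy for the pipeline."""


class SocSafetyError(Exception):
    """Base class for all package errors."""


class VocabularyError(SocSafetyError):
    """A controlled vocabulary failed validation."""


class VocabularySizeError(VocabularyError):
    """SOC vocabulary does not contain exactly the expected 27 entries."""


class DuplicateEntryError(VocabularyError):
    """Two vocabulary records share a key that must be unique."""


class EmptyTermError(SocSafetyError):
    """A term was empty before or after normalization."""


class DictionaryError(SocSafetyError):
    """The term hierarchy failed validation (dangling parent, bad SOC...)."""


class SynonymCollisionError(SocSafetyError):
    """The same synonym maps to two different drugs in the lexicon."""


class AtcFormatError(SocSafetyError):
    """A string does not match the ATC code pattern."""


class FormatError(SocSafetyError):
    """An input file has a malformed header or dialect."""


class EmptyProfileError(SocSafetyError):
    """A Z-score was requested for a drug with zero adverse events."""


class ConfigError(SocSafetyError):
    """A configuration value is out of range or inconsistent."""
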