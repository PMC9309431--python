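"""Exception hierarchy shared across the package.

All data-level failures derive from :class:`Cyp2c19SupError` so callers (and
the CLI) can distinguish bad input from programming errors.
"""


class Cyp2c19SupError(Exception):
    """Base class for all package-specific errors."""


class GenotypeParseError(Cyp2c19SupError):
    """A genotype file could not be parsed (bad token, bad column, bad VCF)."""


class AlleleDomainError(Cyp2c19SupError):
    """An allele outside the defined set for a marker was encountered.

    rs12248560 admits only C/T, rs4244285 only G/A; anything else is a data
    error, never silently recoded.
    """

    def __init__(self, message: str, sample_id: str | None = None,
                 rsid: str | None = None):
        super().__init__(message)
        self.sample_id = sample_id
        self.rsid = rsid


class AmbiguousRecordError(Cyp2c19SupError):
    """The same rsID matched more than one VCF record."""


class UncallableSampleError(Cyp2c19SupError):
    """A sample with a missing genotype slot cannot be haplogenotype-called."""

    def __init__(self, message: str, sample_id: str | None = None):
        super().__init__(message)
        self.sample_id = sample_id


class PhasingError(Cyp2c19SupError):
    """Haplotype inference was requested for a non-phaseable haplogenotype."""


class VocabularyError(Cyp2c19SupError):
    """A token outside a closed vocabulary (drug, indication, ...) was used."""


class StandardDoseUnavailableError(Cyp2c19SupError):
    """No reference standard daily dose exists for the requested drug."""


class FrequencyError(Cyp2c19SupError):
    """Invalid haplotype/population frequency input."""


class EmptyCohortError(Cyp2c19SupError):
    """An operation requiring at least one callable sample got none."""
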