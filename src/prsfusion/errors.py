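"""Exception types shared across the pipeline."""


class PrsFusionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PrsFusionError):
    """Invalid configuration value or combination."""


class DataError(PrsFusionError):
    """Malformed or inconsistent input data."""


class AlleleMismatchError(DataError):
    """Effect alleles cannot be aligned to the dosage coding."""

    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(
            "effect allele cannot be aligned for SNPs: " + ", ".join(self.snp_ids)
        )


class DegenerateMapError(PrsFusionError):
    """A spatial map lacks the sign structure needed downstream."""
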