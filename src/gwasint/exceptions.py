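"""Exception hierarchy for gwasint."""


class GwasintError(Exception):
    """Base class for all gwasint errors."""


class ConfigurationError(GwasintError):
    """Malformed configuration or input file layout (e.g. missing columns)."""


class ValidationError(GwasintError):
    """Input data violate a documented invariant (e.g. p outside (0, 1])."""


class AlignmentError(GwasintError):
    """GWAS and annotation tables cannot be aligned under the requested policy."""
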