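"""Exception hierarchy."""


class AmpEditError(Exception):
    """Base class for all ampedit errors."""


class ConfigError(AmpEditError):
    """Malformed experiment configuration (missing columns, bad parameters)."""


class PanelValidationError(AmpEditError):
    """A panel row violates a sequence invariant (primer/amplicon/protospacer)."""


class FastqError(AmpEditError):
    """Malformed FASTQ input."""
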