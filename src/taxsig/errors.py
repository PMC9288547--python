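"""Exception hierarchy shared across the toolkit."""


class TaxsigError(Exception):
    """Base class for all errors raised by taxsig."""


class ParseError(TaxsigError):
    """Malformed input file (FASTA, partition TSV, pattern table, YAML)."""


class ValidationError(TaxsigError):
    """A domain object violates one of its invariants."""


class DesignError(TaxsigError):
    """Primer design could not proceed."""


class PanelAssemblyError(DesignError):
    """A triplex panel violates an assembly rule; the message names the rule."""


class ConfigError(TaxsigError):
    """A fixture or run configuration is internally inconsistent."""
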