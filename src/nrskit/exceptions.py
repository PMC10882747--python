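"""Exception types raised by nrskit parsers and pipeline stages."""


class NrskitError(Exception):
    """Base class for all nrskit errors."""


class FormatError(NrskitError, ValueError):
    """A malformed on-disk record (rGFA, walk TSV, FASTA, GFF3)."""


class RgfaFormatError(FormatError):
    """Malformed rGFA: missing SN/SO/SR tags, duplicate ids, dangling links."""


class WalkFormatError(FormatError):
    """Malformed walk TSV: unknown segments, inverted intervals, bad columns."""


class PipelineError(NrskitError, ValueError):
    """A pipeline-stage contract violation (bad inputs, unresolvable state)."""
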