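"""Exception hierarchy shared by all evnet stages."""


class EVNetError(Exception):
    """Base class for all evnet errors."""


class ConfigError(EVNetError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(EVNetError):
    """Input data violated a documented precondition."""


class HierarchyError(EVNetError):
    """The signaling-hierarchy rules are undefined for the given inputs
    (e.g. an empty receptor level with a nonempty network)."""


class PipelineError(EVNetError):
    """A pipeline stage failed; the message names the stage."""
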