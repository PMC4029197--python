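"""Exception hierarchy for the genetopics package."""


class GeneTopicsError(Exception):
    """Base class for all errors raised by genetopics."""


class ParseError(GeneTopicsError):
    """An input file could not be parsed; message names the file and line."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{self.path}:{line_no}: {message}")


class ConfigurationError(GeneTopicsError):
    """Inputs or parameters are structurally valid but unusable (e.g. empty index)."""
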