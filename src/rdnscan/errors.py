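"""Exception hierarchy shared across pipeline stages."""


class RdnscanError(Exception):
    """Base class for all package errors."""


class PanelIntegrityError(RdnscanError):
    """Panel metadata / FASTA records are inconsistent or invalid."""


class FormatError(RdnscanError):
    """A file or record does not conform to its declared format."""


class ParameterError(RdnscanError):
    """An argument is outside its documented range."""


class UndefinedRatioError(RdnscanError):
    """log10(I/E) requested with a non-positive depth."""


class StageError(RdnscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
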