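"""Exception hierarchy shared by all beatflow stages.

Two broad categories are distinguished so the CLI can map them onto
distinct exit codes: problems with user-supplied inputs (files, shapes,
configuration values) versus failures arising while processing valid
inputs.
"""


class BeatflowError(Exception):
    """Base class for all beatflow errors."""


class InputError(BeatflowError):
    """Invalid user input: bad files, incompatible shapes, bad config."""


class ProcessingError(BeatflowError):
    """A pipeline stage failed on otherwise valid input."""


class TileShapeError(InputError):
    """Two image tiles passed to a correlation score differ in shape."""


class FrameSizeError(InputError):
    """Frame too small for the requested tiling/search configuration."""


class InsufficientSupportError(ProcessingError):
    """Too few valid flow nodes to support a spline fit."""


class StageError(ProcessingError):
    """Wraps an error with the pipeline stage (and frame) it occurred in."""

    def __init__(self, stage: str, message: str, frame: int | None = None):
        self.stage = stage
        self.frame = frame
        where = f"stage '{stage}'" + (f", frame {frame}" if frame is not None else "")
        super().__init__(f"{where}: {message}")
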