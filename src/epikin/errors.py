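"""Exception types shared across the package."""


class EpikinError(Exception):
    """Base class for package-specific errors."""


class DegenerateSignalError(EpikinError, ValueError):
    """A signal carries no usable oscillatory content (e.g. constant trace)."""


class MissingFramesError(EpikinError, ValueError):
    """A tracker table has gaps in its frame index."""

    def __init__(self, missing_frames):
        self.missing_frames = list(missing_frames)
        shown = ", ".join(str(f) for f in self.missing_frames[:10])
        more = "" if len(self.missing_frames) <= 10 else ", ..."
        super().__init__(f"tracker table is missing frames: {shown}{more}")


class SchemaError(EpikinError, ValueError):
    """A table on disk does not match the expected column schema."""


class ConvergenceError(EpikinError, RuntimeError):
    """An iterative solver hit its iteration cap before converging."""
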