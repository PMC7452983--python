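"""Exception taxonomy shared by the library and the CLI.

The CLI maps each family to a distinct exit code so that a failed stage of
the pipeline can be identified from the shell.
"""


class LinguavolError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(LinguavolError):
    """Invalid user input: files, configs, landmark sets, specs."""

    exit_code = 2


class SegmentationError(LinguavolError):
    """Thresholding / component / cavity extraction failure."""

    exit_code = 3


class GeometryError(LinguavolError):
    """Degenerate or missing landmark geometry."""

    exit_code = 4


class StatsError(LinguavolError):
    """Statistical analysis cannot be run on the given table."""

    exit_code = 5
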