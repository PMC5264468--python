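"""Exception hierarchy; the CLI maps these onto exit codes."""


class XciError(Exception):
    """Base class for all pipeline errors."""


class InputError(XciError, ValueError):
    """Malformed or inconsistent user input (CLI exit code 1)."""


class StageError(XciError, RuntimeError):
    """A pipeline stage failed mid-run (CLI exit code 2)."""
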