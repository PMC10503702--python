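"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but too short/empty/constant to process."""
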