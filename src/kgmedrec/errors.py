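"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A knowledge-graph schema violates its structural invariants."""


class VocabularyError(KeyError):
    """An entity, relation, user or token id is unknown to the model."""


class SamplingError(RuntimeError):
    """Negative sampling could not produce a valid corrupted triple."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, value: float):
        super().__init__(f"non-finite loss {value!r} at epoch {epoch}")
        self.epoch = epoch


class HarnessError(RuntimeError):
    """Evaluation harness misconfiguration (mismatched splits etc.)."""
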