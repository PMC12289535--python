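"""Exception hierarchy shared across the package."""


class InputError(ValueError):
    """Invalid user-supplied data, configuration, or arguments."""


class FitFailureError(RuntimeError):
    """A regression backend failed to fit; carries fold/stage context."""

    def __init__(self, message: str, *, stage: str | None = None,
                 fold: int | None = None) -> None:
        parts = [message]
        if stage is not None:
            parts.append(f"stage={stage}")
        if fold is not None:
            parts.append(f"fold={fold}")
        super().__init__(" | ".join(parts))
        self.stage = stage
        self.fold = fold
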