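"""Training callbacks: early stopping and learning-rate reduction on plateau.

Both are pure state machines over a metric stream, so their semantics can be
verified with stubbed metrics independently of any model.
"""

from __future__ import annotations


class EarlyStopping:
    """Stop when the monitored metric fails to improve for ``patience`` epochs.

    ``mode='max'`` (e.g. validation accuracy): improvement means a strict
    increase over the best seen so far. The epoch index of the best value is
    kept so the trainer can restore the best weights.
    """

    def __init__(self, patience: int = 5, mode: str = "max", min_delta: float = 0.0):
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self.patience = patience
        self.mode = mode
        self.min_delta = min_delta
        self.best = None
        self.best_epoch = None
        self.wait = 0
        self.stopped_epoch = None

    def _improved(self, value: float) -> bool:
        if self.best is None:
            return True
        if self.mode == "max":
            return value > self.best + self.min_delta
        return value < self.best - self.min_delta

    def update(self, epoch: int, value: float) -> bool:
        """Record the metric for ``epoch`` (1-based); return True to stop."""
        if self._improved(value):
            self.best = value
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            self.stopped_epoch = epoch
            return True
        return False


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored loss (mode 'min')."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 3,
                 min_delta: float = 0.0):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = None
        self.wait = 0

    def update(self, value: float) -> float:
        """Record the epoch's loss; return the (possibly reduced) learning rate."""
        if self.best is None or value < self.best - self.min_delta:
            self.best = value
            self.wait = 0
            return self.lr
        self.wait += 1
        if self.wait >= self.patience:
            self.lr *= self.factor
            self.wait = 0
        return self.lr
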