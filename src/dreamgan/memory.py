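"""Two-slot episodic buffer holding the current and previous latent batches."""

from __future__ import annotations

import numpy as np

from .objectives import MixingCoefficients, mix_memories

__all__ = ["EpisodicBuffer"]


class EpisodicBuffer:
    """Stores the Wake latent batch of the current cycle plus the previous one.

    ``store`` shifts current -> previous; retrieval always returns detached
    copies so later network updates cannot alter stored memories.
    """

    def __init__(self):
        self._current: np.ndarray | None = None
        self._previous: np.ndarray | None = None

    @property
    def current(self) -> np.ndarray | None:
        return self._current

    @property
    def previous(self) -> np.ndarray | None:
        return self._previous

    def store(self, z) -> "EpisodicBuffer":
        z = np.array(getattr(z, "data", z), copy=True)
        if self._current is not None and z.shape != self._current.shape:
            raise ValueError(
                f"latent shape {z.shape} differs from stored {self._current.shape}")
        self._previous = self._current
        self._current = z
        return self

    def commit_old(self) -> None:
        """Set previous <- current (Z_old <- Z at the end of a REM phase)."""
        if self._current is None:
            raise RuntimeError("cannot commit from an empty buffer")
        self._previous = self._current.copy()

    def recall_for_nrem(self) -> np.ndarray:
        """Return the current latent batch (single unmixed episodic memories)."""
        if self._current is None:
            raise RuntimeError("episodic buffer is empty")
        return self._current.copy()

    def recall_for_rem(self, coeffs: MixingCoefficients,
                       rng: np.random.Generator) -> np.ndarray:
        """Mix current and previous memories with fresh standard-normal noise.

        On the first cycle (no previous batch yet) the current batch is
        returned unchanged.
        """
        if self._current is None:
            raise RuntimeError("episodic buffer is empty")
        if self._previous is None:
            return self._current.copy()
        eps = rng.standard_normal(self._current.shape)
        return mix_memories(self._current, self._previous, eps, coeffs)
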