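"""Fixed analysis / baseline window grids.

All trial-level features (power and iCoh) are averaged inside seven 0.5 s
windows centered on the go cue with 50 % overlap; dB baseline power uses
three 0.5 s windows preceding the pre-movement (neurofeedback) phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Seven 0.5 s analysis windows spanning [-1, +1] s around the go cue,
#: 50 % overlap.
ANALYSIS_WINDOWS: tuple[tuple[float, float], ...] = (
    (-1.00, -0.50),
    (-0.75, -0.25),
    (-0.50, 0.00),
    (-0.25, 0.25),
    (0.00, 0.50),
    (0.25, 0.75),
    (0.50, 1.00),
)

#: Baseline windows relative to the onset of the pre-movement phase,
#: as printed in the protocol.
BASELINE_WINDOWS: tuple[tuple[float, float], ...] = (
    (-1.50, -1.00),
    (-0.75, -0.25),
    (-0.50, 0.00),
)

#: The first four analysis windows end at or before +0.25 s; used for the
#: "pre-go-cue" window-subset variant.
PRE_GO_CUE_WINDOWS: tuple[tuple[float, float], ...] = ANALYSIS_WINDOWS[:4]


@dataclass(frozen=True)
class WindowGrid:
    """An ordered set of [start, end] windows (seconds, event-relative)."""

    windows: tuple[tuple[float, float], ...] = ANALYSIS_WINDOWS
    baseline_windows: tuple[tuple[float, float], ...] = BASELINE_WINDOWS

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def slices(self, fs: float, t0: float, n_samples: int,
               which: str = "analysis") -> list[slice]:
        """Sample slices for each window on a time axis t0 + k/fs.

        Each 0.5 s window maps to exactly ``round(0.5 * fs)`` samples
        (start-inclusive), so 50 %-overlapping windows share exactly half
        their samples.
        """
        wins = self.windows if which == "analysis" else self.baseline_windows
        out = []
        for (a, b) in wins:
            i0 = int(round((a - t0) * fs))
            n = int(round((b - a) * fs))
            i1 = i0 + n
            if i0 < 0 or i1 > n_samples:
                raise ValueError(
                    f"window [{a}, {b}] s lies outside the epoch "
                    f"(t0={t0}, n={n_samples}, fs={fs})")
            out.append(slice(i0, i1))
        return out

    def labels(self, which: str = "analysis") -> list[str]:
        wins = self.windows if which == "analysis" else self.baseline_windows
        return [f"[{a:+.2f},{b:+.2f}]" for a, b in wins]


def window_means(x: np.ndarray, slices: list[slice]) -> np.ndarray:
    """Average the last axis of ``x`` inside each slice; stacks on a new
    trailing axis (… , n_windows)."""
    return np.stack([x[..., s].mean(axis=-1) for s in slices], axis=-1)
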