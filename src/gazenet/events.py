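"""Fixation / saccade / regression detection and the six classic metrics.

Fixations are found with the dispersion-threshold algorithm (I-DT): a
window of consecutive samples is a fixation when the gaze is held for at
least 100 ms with all shifts inside a 40-pixel box.  Both thresholds are
inclusive ("at least" 100 ms; box edge counts as inside).  Saccades are
the movements between consecutive fixations, with amplitude the
Euclidean distance between the two fixation centroids.  A saccade is a
regression — a backward movement toward previously visited items — when
it lands at least one stimulus-cell width to the left within the same
row, or at least half a row height above the launch point (screen y
grows downward).

Event detection never filters the sample series itself: network
construction downstream operates on raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_io import GazeSeries

__all__ = [
    "Fixation",
    "Saccade",
    "RegressionRule",
    "TraditionalMetrics",
    "detect_fixations",
    "extract_saccades",
    "traditional_metrics",
]

DISPERSION_PX = 40.0
MIN_FIX_MS = 100.0


@dataclass(frozen=True)
class Fixation:
    start: float  # ms
    end: float  # ms
    centroid: tuple  # (x, y) px
    n_samples: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Saccade:
    from_fix: int
    to_fix: int
    amplitude: float  # px, centroid-to-centroid
    is_regression: bool


@dataclass(frozen=True)
class RegressionRule:
    """Operationalizes "backward eye movements" for a left-to-right,
    top-to-bottom scan: leftward by >= one cell width within the row, or
    upward by >= half a row height."""

    cell_width_px: float = 160.0
    row_height_px: float = 180.0

    def is_regression(self, launch, landing) -> bool:
        dx = landing[0] - launch[0]
        dy = landing[1] - launch[1]
        within_row_back = dx <= -self.cell_width_px and abs(dy) < self.row_height_px / 2
        row_return = dy <= -self.row_height_px / 2
        return bool(within_row_back or row_return)


@dataclass
class TraditionalMetrics:
    """The six classic summary metrics of a RAN recording."""

    total_time: float  # s
    avg_fix_duration: float  # ms; NaN if no fixations
    fixation_counts: int
    avg_saccade_amplitude: float  # px; NaN if no saccades
    saccade_counts: int
    regression_counts: int

    def as_dict(self) -> dict:
        return {
            "total_time": self.total_time,
            "avg_fix_duration": self.avg_fix_duration,
            "fixation_counts": self.fixation_counts,
            "avg_saccade_amplitude": self.avg_saccade_amplitude,
            "saccade_counts": self.saccade_counts,
            "regression_counts": self.regression_counts,
        }


METRIC_COLUMNS = (
    "total_time",
    "avg_fix_duration",
    "fixation_counts",
    "avg_saccade_amplitude",
    "saccade_counts",
    "regression_counts",
)


def detect_fixations(
    series: GazeSeries,
    dispersion_px: float = DISPERSION_PX,
    min_dur_ms: float = MIN_FIX_MS,
) -> list[Fixation]:
    """I-DT sliding-window fixation detection on a preprocessed series.

    The window grows while the bounding box of its samples stays within
    ``dispersion_px`` on both axes; it is emitted as a fixation when its
    time span reaches ``min_dur_ms``.  Returns time-ordered, disjoint
    fixations; a series shorter than the duration threshold yields an
    empty list.
    """
    t, x, y = series.t, series.x, series.y
    n = len(t)
    fixations: list[Fixation] = []
    i = 0
    while i < n:
        # smallest window starting at i that spans min_dur_ms
        j = i
        while j + 1 < n and t[j] - t[i] < min_dur_ms:
            j += 1
        if t[j] - t[i] < min_dur_ms:
            break  # tail too short for any further fixation
        wx, wy = x[i : j + 1], y[i : j + 1]
        if (wx.max() - wx.min()) <= dispersion_px and (wy.max() - wy.min()) <= dispersion_px:
            xmin, xmax = wx.min(), wx.max()
            ymin, ymax = wy.min(), wy.max()
            while j + 1 < n:
                nx, ny = x[j + 1], y[j + 1]
                if (
                    max(xmax, nx) - min(xmin, nx) <= dispersion_px
                    and max(ymax, ny) - min(ymin, ny) <= dispersion_px
                ):
                    j += 1
                    xmin, xmax = min(xmin, nx), max(xmax, nx)
                    ymin, ymax = min(ymin, ny), max(ymax, ny)
                else:
                    break
            fixations.append(
                Fixation(
                    start=float(t[i]),
                    end=float(t[j]),
                    centroid=(float(x[i : j + 1].mean()), float(y[i : j + 1].mean())),
                    n_samples=j - i + 1,
                )
            )
            i = j + 1
        else:
            i += 1
    return fixations


def extract_saccades(
    fixations: list[Fixation], rule: RegressionRule | None = None
) -> list[Saccade]:
    """One saccade per consecutive fixation pair; fewer than two
    fixations yield an empty list."""
    rule = rule or RegressionRule()
    out = []
    for k in range(len(fixations) - 1):
        a, b = fixations[k], fixations[k + 1]
        amp = float(np.hypot(b.centroid[0] - a.centroid[0], b.centroid[1] - a.centroid[1]))
        out.append(
            Saccade(
                from_fix=k,
                to_fix=k + 1,
                amplitude=amp,
                is_regression=rule.is_regression(a.centroid, b.centroid),
            )
        )
    return out


def traditional_metrics(
    series: GazeSeries,
    fixations: list[Fixation] | None = None,
    saccades: list[Saccade] | None = None,
    rule: RegressionRule | None = None,
) -> TraditionalMetrics:
    """Compute the six classic metrics; events are detected if not given.

    total time of naming = span of the recording in seconds; averages are
    arithmetic means and reported as NaN when there is nothing to
    average.
    """
    if fixations is None:
        fixations = detect_fixations(series)
    if saccades is None:
        saccades = extract_saccades(fixations, rule)
    durs = np.array([f.duration for f in fixations])
    amps = np.array([s.amplitude for s in saccades])
    return TraditionalMetrics(
        total_time=series.duration_ms / 1000.0,
        avg_fix_duration=float(durs.mean()) if len(durs) else float("nan"),
        fixation_counts=len(fixations),
        avg_saccade_amplitude=float(amps.mean()) if len(amps) else float("nan"),
        saccade_counts=len(saccades),
        regression_counts=int(sum(s.is_regression for s in saccades)),
    )
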