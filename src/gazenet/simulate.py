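"""Synthetic rapid-automatized-naming (RAN) gaze recordings.

Emulates the scanning behavior the task instructions induce: a 5 x 10
stimulus matrix named serially left-to-right within each row and
top-to-bottom across rows, with a fixation dwell on each stimulus,
saccadic jumps between stimuli (a few in-flight samples at 90 Hz),
occasional refixations of the same stimulus, occasional regressions to
an earlier stimulus, Gaussian within-fixation jitter, and per-sample
tracking dropout.

Dwell durations are log-normal: empirical fixation-duration
distributions are right-skewed, and the log-normal is the standard
parsimonious choice.  Task types differ by multipliers on the dwell
median and refixation probability — non-alphanumeric naming (objects,
colors) requires conceptual processing before phonological access and
therefore runs slower, with more and longer fixations, than
alphanumeric naming (numbers, characters).

The generator returns ground truth (dwell episodes, regression events)
alongside the series so detector recovery can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .gaze_io import GazeSeries, TASKS

__all__ = [
    "TaskProfile",
    "TASK_PROFILES",
    "SimulationConfig",
    "CohortSpec",
    "SimulationResult",
    "simulate_subject",
    "simulate_cohort",
    "duration_spanning_configs",
]


@dataclass(frozen=True)
class TaskProfile:
    """Multipliers applied to the base config for one task type."""

    dwell_mult: float = 1.0
    refix_mult: float = 1.0


#: Non-alphanumeric naming is slower: dwell median x1.6, refixations x1.5.
#: Numbers are the most automatized stimulus class, hence slightly faster
#: than characters.
TASK_PROFILES: dict[str, TaskProfile] = {
    "N-num": TaskProfile(0.85, 1.0),
    "N-cha": TaskProfile(1.0, 1.0),
    "N-obj": TaskProfile(1.6, 1.5),
    "N-col": TaskProfile(1.55, 1.5),
}


@dataclass
class SimulationConfig:
    """Parameters of one simulated recording.

    grid
        Stimulus matrix (rows, cols); the RAN card is 5 x 10.
    cell
        Stimulus spacing (width, height) in px; the grid is centered on
        the screen.
    rate
        Sampling rate, Hz (Tobii-4C-class tracker: 90).
    dwell_median_ms, dwell_sigma
        Log-normal per-stimulus fixation duration; median in ms, sigma
        on the log scale.
    refix_prob
        Probability of a second, offset fixation on the same stimulus.
    regress_prob
        Probability of a backward glance to an earlier stimulus after a
        stimulus is named.
    jitter_sd
        Within-fixation positional noise, px.
    dropout_prob
        Per-sample probability of an invalid (lost-tracking) sample.
    n_transit
        Inclusive range of in-flight samples per saccade; at 90 Hz a
        20-30 ms saccade spans about 2 samples.
    """

    grid: tuple = (5, 10)
    cell: tuple = (160.0, 180.0)
    rate: float = 90.0
    screen: tuple = (1920, 1080)
    dwell_median_ms: float = 320.0
    dwell_sigma: float = 0.35
    refix_prob: float = 0.12
    refix_dwell_frac: float = 0.5
    regress_prob: float = 0.08
    regress_dwell_frac: float = 0.6
    jitter_sd: float = 5.0
    center_sd: float = 8.0
    refix_offset_px: float = 30.0
    dropout_prob: float = 0.02
    n_transit: tuple = (2, 3)
    task: str = ""
    seed: int = 0

    def __post_init__(self):
        for p in (self.refix_prob, self.regress_prob, self.dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dwell_median_ms <= 0 or self.dwell_sigma <= 0:
            raise ValueError("dwell distribution parameters must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if min(self.grid) < 1:
            raise ValueError("grid must have at least one row and column")

    def with_task(self, task: str) -> "SimulationConfig":
        """Apply the task-type profile multipliers."""
        prof = TASK_PROFILES[task]
        return dataclasses.replace(
            self,
            task=task,
            dwell_median_ms=self.dwell_median_ms * prof.dwell_mult,
            refix_prob=min(1.0, self.refix_prob * prof.refix_mult),
        )

    def cell_centers(self) -> np.ndarray:
        """(rows*cols, 2) stimulus centers in row-major scan order."""
        rows, cols = self.grid
        cw, ch = self.cell
        w, h = self.screen
        x0 = (w - (cols - 1) * cw) / 2.0
        y0 = (h - (rows - 1) * ch) / 2.0
        cx = x0 + cw * np.arange(cols)
        cy = y0 + ch * np.arange(rows)
        xx, yy = np.meshgrid(cx, cy)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class CohortSpec:
    """A simulated cohort: n subjects x a set of tasks.

    Per-subject dwell and regression tendencies are drawn once (log-normal
    multipliers with ``between_subject_sd`` on the log scale) and shared
    across that subject's tasks, so tasks remain paired within subject.
    """

    n_subjects: int = 20
    tasks: tuple = TASKS
    base_config: SimulationConfig = field(default_factory=SimulationConfig)
    between_subject_sd: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")


@dataclass
class SimulationResult:
    """A simulated recording plus its generating ground truth."""

    series: GazeSeries
    n_dwells: int
    n_regressions: int
    dwell_ms: np.ndarray  # duration of every fixation episode

    @property
    def naming_time_s(self) -> float:
        return self.series.duration_ms / 1000.0


def _dwell_draw(rng, cfg: SimulationConfig, frac: float = 1.0) -> float:
    return frac * cfg.dwell_median_ms * float(
        np.exp(rng.normal(0.0, cfg.dwell_sigma))
    )


def simulate_subject(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Simulate one recording of one subject naming one RAN card.

    The fixation-episode sequence visits all stimulus cells in row-major
    order; regressions insert a brief revisit of an earlier cell before
    the scan resumes.  Samples fall on the regular 1000/rate ms grid so
    total duration is the sum of dwells plus saccadic transit time.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    centers = cfg.cell_centers()
    n_stim = len(centers)

    # fixation episodes: (target xy, dwell ms, preceded-by-regression flag)
    episodes: list[tuple[np.ndarray, float]] = []
    n_regress = 0
    for idx in range(n_stim):
        episodes.append((centers[idx], _dwell_draw(rng, cfg)))
        if rng.random() < cfg.refix_prob:
            ang = rng.uniform(0, 2 * np.pi)
            off = cfg.refix_offset_px * np.array([np.cos(ang), np.sin(ang)])
            episodes.append(
                (centers[idx] + off, _dwell_draw(rng, cfg, cfg.refix_dwell_frac))
            )
        if idx > 0 and idx < n_stim - 1 and rng.random() < cfg.regress_prob:
            back = int(rng.integers(max(0, idx - 8), idx))
            episodes.append(
                (centers[back], _dwell_draw(rng, cfg, cfg.regress_dwell_frac))
            )
            n_regress += 1

    dt = 1000.0 / cfg.rate
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    dwells = []
    prev_pos = None
    lo, hi = cfg.n_transit
    for target, dwell in episodes:
        pos = target + rng.normal(0.0, cfg.center_sd, size=2)
        if prev_pos is not None and hi > 0:
            n_tr = int(rng.integers(lo, hi + 1)) if hi > lo else hi
            if n_tr > 0:
                frac = np.arange(1, n_tr + 1) / (n_tr + 1)
                xs.append(prev_pos[0] + frac * (pos[0] - prev_pos[0]))
                ys.append(prev_pos[1] + frac * (pos[1] - prev_pos[1]))
        n_smp = max(1, int(round(dwell / dt)))
        xs.append(pos[0] + rng.normal(0.0, cfg.jitter_sd, size=n_smp))
        ys.append(pos[1] + rng.normal(0.0, cfg.jitter_sd, size=n_smp))
        dwells.append(dwell)
        prev_pos = pos

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = len(x)
    t = dt * np.arange(n)
    valid = rng.random(n) >= cfg.dropout_prob
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    if not valid.any():  # pathological dropout config
        valid[0] = True
        x[0], y[0] = centers[0]
    series = GazeSeries(
        t=t,
        x=x,
        y=y,
        valid=valid,
        rate=cfg.rate,
        screen=cfg.screen,
        task=cfg.task,
    )
    return SimulationResult(
        series=series,
        n_dwells=len(episodes),
        n_regressions=n_regress,
        dwell_ms=np.asarray(dwells),
    )


def simulate_cohort(spec: CohortSpec) -> dict[tuple, SimulationResult]:
    """Simulate every (subject, task) recording of a cohort.

    Returns a dict keyed by ``(subject_id, task)``.  Each subject gets an
    independent RNG stream derived from ``(spec.seed, subject index)`` so
    adding subjects never perturbs existing ones.
    """
    out: dict[tuple, SimulationResult] = {}
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:03d}"
        subj_rng = np.random.default_rng([spec.seed, i])
        dwell_mult = float(np.exp(subj_rng.normal(0.0, spec.between_subject_sd)))
        beh_mult = float(np.exp(subj_rng.normal(0.0, spec.between_subject_sd)))
        for j, task in enumerate(spec.tasks):
            cfg = dataclasses.replace(
                spec.base_config,
                dwell_median_ms=spec.base_config.dwell_median_ms * dwell_mult,
                regress_prob=min(1.0, spec.base_config.regress_prob * beh_mult),
                refix_prob=min(1.0, spec.base_config.refix_prob * beh_mult),
            ).with_task(task)
            res = simulate_subject(cfg, rng=np.random.default_rng([spec.seed, i, j]))
            res.series.subject_id = sid
            out[(sid, task)] = res
    return out


def duration_spanning_configs(
    n_subjects: int,
    t_min_s: float = 10.0,
    t_max_s: float = 60.0,
    task: str = "N-num",
    base: SimulationConfig | None = None,
) -> list[SimulationConfig]:
    """Configs whose expected naming times span [t_min_s, t_max_s].

    Used to probe how network size scales with naming time: the dwell
    median is set per subject so that the expected total dwell (50
    stimuli x mean dwell) hits a log-spaced target duration.
    """
    base = base or SimulationConfig()
    n_stim = base.grid[0] * base.grid[1]
    mean_over_median = float(np.exp(base.dwell_sigma**2 / 2))
    targets = np.geomspace(t_min_s, t_max_s, n_subjects)
    cfgs = []
    for i, tgt in enumerate(targets):
        med = tgt * 1000.0 / (n_stim * mean_over_median)
        cfgs.append(
            dataclasses.replace(base, dwell_median_ms=med, task=task, seed=i)
        )
    return cfgs
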