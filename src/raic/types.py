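"""Domain containers shared across the pipeline.

Coordinate convention: origin at the top-left of the display, x rightward,
y downward, units of pixels, canvas 1920 x 1080 unless stated otherwise.
Ellipse orientation is the angle of the major axis measured from the +x
axis toward +y, reported modulo pi in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANVAS = (1920, 1080)  # (width, height) px


@dataclass(frozen=True)
class ROI:
    """One elliptical region of interest, a state of the scanpath HMM."""

    index: int  # 1-based position along the expert path
    cx: float
    cy: float
    major_axis_length: float  # full length, px
    minor_axis_length: float
    orientation: float  # radians, modulo pi

    def __post_init__(self) -> None:
        if self.major_axis_length <= 0 or self.minor_axis_length <= 0:
            raise ValueError(f"ROI {self.index}: axis lengths must be positive")


@dataclass
class ExpertGazePattern:
    """Ordered elliptical ROIs defining the expert viewing path.

    The ROI order is the path order; the ROIs double as the (fixed) state
    space of every participant HMM fitted for this image.
    """

    image_id: str
    rois: list[ROI]
    source_expert_id: str | None = None

    def __post_init__(self) -> None:
        n = len(self.rois)
        if not 1 <= n <= 14:
            raise ValueError(f"{self.image_id}: expected 1..14 ROIs, got {n}")
        indices = [r.index for r in self.rois]
        if indices != list(range(1, n + 1)):
            raise ValueError(f"{self.image_id}: ROI indices must be 1..{n} in order")

    @property
    def n_states(self) -> int:
        return len(self.rois)


@dataclass
class FixationSequence:
    """One participant x image trial: ordered fixations with positions/times."""

    participant_id: str
    image_id: str
    condition: str  # "colour" | "grayscale"
    x: np.ndarray  # px
    y: np.ndarray
    onset_ms: np.ndarray
    duration_ms: np.ndarray
    trial_length_ms: float = 30_000.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        self.duration_ms = np.asarray(self.duration_ms, dtype=float)
        if len({len(self.x), len(self.y), len(self.onset_ms), len(self.duration_ms)}) != 1:
            raise ValueError("fixation fields must have equal length")
        if len(self.onset_ms) and np.any(np.diff(self.onset_ms) <= 0):
            raise ValueError("fixation onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset_ms)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class GazeHMM:
    """HMM over a fixed ROI state space with Dirichlet posteriors.

    Emissions are fixed 2-D Gaussians derived from the ROI geometry and are
    never re-estimated; only the prior ``pi`` and transition matrix ``A``
    carry posterior uncertainty (symmetric Dirichlet prior of strength
    ``prior_strength`` on ``pi`` and on each row of ``A``).
    """

    means: np.ndarray  # (n, 2)
    covs: np.ndarray  # (n, 2, 2)
    alpha: np.ndarray  # Dirichlet posterior over pi, (n,)
    beta: np.ndarray  # Dirichlet posteriors over A rows, (n, n)
    prior_strength: float = 1.0
    window_s: tuple[float, float] | None = None
    occupancy: np.ndarray | None = None  # expected state occupancy, (n,)
    n_obs: int = 0
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_states(self) -> int:
        return len(self.alpha)

    @property
    def pi(self) -> np.ndarray:
        """Posterior-mean initial-state distribution."""
        return self.alpha / self.alpha.sum()

    @property
    def A(self) -> np.ndarray:
        """Posterior-mean transition matrix (row stochastic)."""
        return self.beta / self.beta.sum(axis=1, keepdims=True)


@dataclass
class EvaluationGroups:
    """High/middle/low rating-group assignment for one image x attribute."""

    image_id: str
    attribute: str
    assignment: dict[str, str]  # participant_id -> "high" | "middle" | "low"
    centroids: dict[str, float]
    degenerate: bool = False

    def members(self, group: str) -> list[str]:
        return sorted(p for p, g in self.assignment.items() if g == group)

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in ("high", "middle", "low")}


@dataclass
class PupilTrace:
    """One trial's pupil series (300 Hz) plus the pre-trial rest trace."""

    participant_id: str
    image_id: str
    eye: str  # "left" | "right"
    samples: np.ndarray  # raw, a.u.; NaN marks missing
    rest_trace: np.ndarray
    fs: float = 300.0
    baseline: float | None = None
    processed: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    usable: bool = True
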