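"""Protocol representation for the hexagonal global saccadic-adaptation task.

A session consists of four blocks (baseline, two adaptation blocks, baseline)
of saccades around a clockwise hexagonal path.  During adaptation blocks the
target is displaced intrasaccadically, either further along the saccade
trajectory (gain-up) or back towards the previous fixation (gain-down).
Displacement magnitudes are expressed throughout as relative-gain
perturbations ``p`` (post-displacement relative gain minus one): with the
default geometry (10 dva inter-target distance, +3.3 / −2.5 dva
displacements) the two directions produce p = +0.33 and p = −0.25, i.e. equal
relative gains in both directions (7.5/10 ≈ 10/13.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SACCADE_TYPES = ("reactive", "scanning")
DIRECTION_ORDERS = ("down-up", "up-down")

#: default block lengths: baseline, adaptation, adaptation, baseline
DEFAULT_N_BASELINE = 48
DEFAULT_N_ADAPTATION = 96


@dataclass(frozen=True)
class Timing:
    """Trial timing parameters (milliseconds unless noted).

    The fixation interval is drawn from a shifted exponential distribution
    (minimum ``fixation_min_ms``, mean ``fixation_mean_ms``) to make target
    onset unpredictable.  After the currently fixated target flashes,
    saccades are polled online with a displacement threshold of
    ``saccade_poll_threshold_dva`` until ``poll_timeout_ms``; the awareness
    probe appears ``probe_delay_ms`` after the intrasaccadic displacement.
    """

    fixation_min_ms: float = 250.0
    fixation_mean_ms: float = 550.0
    flash_duration_ms: float = 150.0
    saccade_poll_threshold_dva: float = 1.5
    poll_timeout_ms: float = 2750.0
    probe_delay_ms: float = 500.0
    response_window_ms: float = 2000.0


@dataclass(frozen=True)
class Block:
    """One experimental block: index (1..4), length and per-trial perturbation."""

    index: int
    n_trials: int
    perturbation: np.ndarray

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError(f"block {self.index}: n_trials must be positive")
        if len(self.perturbation) != self.n_trials:
            raise ValueError("perturbation length must equal n_trials")


def hexagon_vertices(inter_target_distance: float = 10.0) -> np.ndarray:
    """Vertices of the clockwise hexagonal saccade path, screen-centred.

    For a regular hexagon the side length equals the circumradius, so
    neighbouring vertices are exactly ``inter_target_distance`` apart.  The
    path starts at the central-lower vertex and proceeds clockwise (angles
    decreasing, y axis pointing up).

    Returns
    -------
    ndarray, shape (6, 2)
        Vertex positions in dva.
    """
    k = np.arange(6)
    angles = np.deg2rad(-90.0 - 60.0 * k)
    return inter_target_distance * np.stack([np.cos(angles), np.sin(angles)], axis=1)


@dataclass(frozen=True)
class ProtocolSpec:
    """Full description of one experimental session.

    Attributes
    ----------
    saccade_type : {"reactive", "scanning"}
        Whether saccades are cued by a single jumping target (reactive) or
        selected among six persistent targets (scanning).
    direction_order : {"down-up", "up-down"}
        Order of the two adaptation blocks.
    blocks : tuple of Block
        The four blocks with per-trial perturbations.
    hexagon : ndarray (6, 2)
        Target vertex positions (dva).
    """

    saccade_type: str
    direction_order: str
    blocks: tuple[Block, ...]
    hexagon: np.ndarray
    inter_target_distance: float
    displacement_forward: float
    displacement_backward: float
    timing: Timing = field(default_factory=Timing)

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def perturbation(self) -> np.ndarray:
        """Per-trial perturbation over the whole session, in gain units."""
        return np.concatenate([b.perturbation for b in self.blocks])

    @property
    def block_index(self) -> np.ndarray:
        """Per-trial block label (1..4)."""
        return np.concatenate(
            [np.full(b.n_trials, b.index, dtype=int) for b in self.blocks]
        )

    @property
    def gain_up_perturbation(self) -> float:
        return self.displacement_forward / self.inter_target_distance

    @property
    def gain_down_perturbation(self) -> float:
        return -self.displacement_backward / self.inter_target_distance

    def block_gain_direction(self, block: int) -> str:
        """Gain direction label for a block: 'none', 'down' or 'up'."""
        if block in (1, 4):
            return "none"
        first, second = self.direction_order.split("-")
        return first if block == 2 else second

    def trial_geometry(self) -> dict[str, np.ndarray]:
        """Per-trial target geometry for the whole session.

        Returns arrays of length ``n_trials``: hexagon ``direction`` (1..6,
        the edge being traversed), the currently fixated pre-saccadic target
        ``fix``, the pre-displacement goal ``goal_pre`` and the displaced goal
        ``goal_post`` (equal to ``goal_pre`` in baseline blocks).
        """
        n = self.n_trials
        t = np.arange(n)
        start_idx = t % 6
        goal_idx = (t + 1) % 6
        fix = self.hexagon[start_idx]
        goal_pre = self.hexagon[goal_idx]
        u = (goal_pre - fix) / self.inter_target_distance
        p = self.perturbation
        goal_post = goal_pre + u * (p * self.inter_target_distance)[:, None]
        return {
            "direction": start_idx + 1,
            "fix": fix,
            "goal_pre": goal_pre,
            "goal_post": goal_post,
        }


def build_protocol(
    saccade_type: str,
    direction_order: str,
    *,
    n_baseline: int = DEFAULT_N_BASELINE,
    n_adaptation: int = DEFAULT_N_ADAPTATION,
    inter_target_distance: float = 10.0,
    displacement_forward: float = 3.3,
    displacement_backward: float = 2.5,
    timing: Timing | None = None,
) -> ProtocolSpec:
    """Build a four-block session protocol.

    Parameters
    ----------
    saccade_type : {"reactive", "scanning"}
    direction_order : {"down-up", "up-down"}
        Gain direction of the first and second adaptation block.
    n_baseline, n_adaptation : int
        Trials per baseline / adaptation block (defaults 48 and 96).
    displacement_forward, displacement_backward : float
        Intrasaccadic displacement magnitudes in dva (gain-up is applied
        further along the saccade trajectory, gain-down back towards the
        origin).  Setting both to 0 yields an unperturbed session.

    Raises
    ------
    ValueError
        For unknown enum values or non-positive trial counts.
    """
    if saccade_type not in SACCADE_TYPES:
        raise ValueError(f"unknown saccade_type {saccade_type!r}; expected one of {SACCADE_TYPES}")
    if direction_order not in DIRECTION_ORDERS:
        raise ValueError(
            f"unknown direction_order {direction_order!r}; expected one of {DIRECTION_ORDERS}"
        )
    if n_baseline <= 0 or n_adaptation <= 0:
        raise ValueError("trial counts must be positive")
    if inter_target_distance <= 0:
        raise ValueError("inter_target_distance must be positive")
    if displacement_forward < 0 or displacement_backward < 0:
        raise ValueError("displacement magnitudes must be non-negative")

    p_by_direction = {
        "up": displacement_forward / inter_target_distance,
        "down": -displacement_backward / inter_target_distance,
    }
    first, second = direction_order.split("-")
    blocks = (
        Block(1, n_baseline, np.zeros(n_baseline)),
        Block(2, n_adaptation, np.full(n_adaptation, p_by_direction[first])),
        Block(3, n_adaptation, np.full(n_adaptation, p_by_direction[second])),
        Block(4, n_baseline, np.zeros(n_baseline)),
    )
    return ProtocolSpec(
        saccade_type=saccade_type,
        direction_order=direction_order,
        blocks=blocks,
        hexagon=hexagon_vertices(inter_target_distance),
        inter_target_distance=inter_target_distance,
        displacement_forward=displacement_forward,
        displacement_backward=displacement_backward,
        timing=timing or Timing(),
    )
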