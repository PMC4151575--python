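"""Stimulation-command state machine driven by the perception outputs.

Turns the tracked hand state and the grasp decision into a timed stream of
stimulation commands against a mock stimulator transport: while the user
reaches, hand-opening commands for the selected grasp pattern are emitted
with aperture and orientation targets; when the hand comes within the
trigger distance of the object the closing pattern is triggered; after a
per-object hold time the release pattern fires and the control loop
restarts.  Real stimulator transport (Bluetooth, electrode-pad patterns) is
out of scope — commands are plain records, serializable to JSONL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .grasp_classify import GraspDecision
from .hand_track import HandState

PATTERNS = (
    "open_palmar",
    "open_lateral",
    "open_pinch",
    "open_spherical",
    "close_palmar",
    "close_lateral",
    "close_pinch",
    "close_spherical",
    "release",
    "idle",
)

IDLE, REACH, HOLD = "IDLE", "REACH", "HOLD"


@dataclass
class StimulationCommand:
    timestamp: float  # s
    pattern: str
    aperture_target: float = 0.0  # mm
    pronation_target: float = 0.0  # deg
    flexion_target: float = 0.0  # deg
    trigger: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class ControllerConfig:
    trigger_distance: float = 50.0  # mm hand-to-object distance that triggers closing
    hold_time: float = 3.0  # s before automatic release (per object type in practice)
    command_rate: float = 10.0  # Hz
    hand_lost_timeout: float = 1.0  # s of lost tracking before reverting to IDLE

    def __post_init__(self) -> None:
        if self.trigger_distance <= 0 or self.hold_time <= 0:
            raise ValueError("trigger_distance and hold_time must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.command_rate


@dataclass
class ControllerState:
    phase: str = IDLE
    t: float = 0.0
    close_time: float | None = None
    hand_lost_since: float | None = None


def step(
    state: ControllerState,
    hand: HandState | None,
    decision: GraspDecision | None,
    target: np.ndarray | None,
    cfg: ControllerConfig,
) -> tuple[ControllerState, list[StimulationCommand]]:
    """One control tick; returns the updated state and emitted commands.

    The command grammar over a full cycle is ``open+ close release``:
    opening commands during the reach, one triggered closing command at the
    distance crossing, one release after the hold time.  Losing the hand for
    longer than ``hand_lost_timeout`` during the reach reverts to IDLE with
    a release-safe command.
    """
    cmds: list[StimulationCommand] = []
    t = state.t

    if state.phase == IDLE:
        if hand is not None and decision is not None:
            state.phase = REACH
            state.hand_lost_since = None
            cmds.append(_open_command(t, hand, decision))
    elif state.phase == REACH:
        if hand is None:
            if state.hand_lost_since is None:
                state.hand_lost_since = t
            elif t - state.hand_lost_since > cfg.hand_lost_timeout:
                # revert with a neutral (release-safe) command; an actual
                # release pattern is only valid after a close
                state.phase = IDLE
                state.hand_lost_since = None
                cmds.append(StimulationCommand(t, "idle"))
        else:
            state.hand_lost_since = None
            dist = float(np.linalg.norm(hand.reference_point - np.asarray(target)))
            if dist <= cfg.trigger_distance:
                cmds.append(
                    StimulationCommand(
                        t,
                        f"close_{decision.grasp_type}",
                        aperture_target=decision.aperture,
                        trigger=True,
                    )
                )
                state.phase = HOLD
                state.close_time = t
            else:
                cmds.append(_open_command(t, hand, decision))
    elif state.phase == HOLD:
        if state.close_time is not None and t - state.close_time >= cfg.hold_time - 1e-9:
            cmds.append(StimulationCommand(t, "release"))
            state.phase = IDLE  # the control loop restarts
            state.close_time = None
    state.t = t + cfg.dt
    return state, cmds


def _open_command(t: float, hand: HandState, decision: GraspDecision) -> StimulationCommand:
    return StimulationCommand(
        t,
        f"open_{decision.grasp_type}",
        aperture_target=decision.aperture,
        pronation_target=0.0 if np.isnan(hand.pronation) else float(hand.pronation),
        flexion_target=0.0 if np.isnan(hand.flexion) else float(hand.flexion),
    )


def run_episode(
    hands: list[HandState | None],
    decision: GraspDecision,
    target: np.ndarray,
    cfg: ControllerConfig | None = None,
) -> list[StimulationCommand]:
    """Run the controller over a pre-computed hand-state trajectory."""
    cfg = cfg or ControllerConfig()
    state = ControllerState()
    log: list[StimulationCommand] = []
    for hand in hands:
        state, cmds = step(state, hand, decision, target, cfg)
        log.extend(cmds)
    return log


def command_grammar(log: list[StimulationCommand]) -> str:
    """Compact grammar string of a command log, e.g. ``'o o o c r'``."""
    out = []
    for c in log:
        if c.pattern.startswith("open_"):
            out.append("o")
        elif c.pattern.startswith("close_"):
            out.append("c")
        elif c.pattern == "release":
            out.append("r")
        else:
            out.append("i")
    return " ".join(out)


def write_jsonl(log: list[StimulationCommand], path) -> None:
    with open(path, "w") as fh:
        for c in log:
            fh.write(c.to_json() + "\n")
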