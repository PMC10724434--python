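"""User-facing control logic: the 4x8 communication board and functional mode.

The communication board shows a highlight that moves in cardinal directions
with the up/down/left/right commands, turns green (selection) on enter, and
yellow (deselection) on back.  In communication-board mode the application
enforces the enter->back rule: any command decoded right after an enter is
treated as back, so a selection is always explicitly dismissed before the
cursor moves again.  In functional-control mode the rule is disabled
(directional commands stay valid after enter); the session starts only after
three consecutive enter commands, and once the TV icon is selected all
further commands are relayed to the TV application instead of the board.

The cursor is clamped at the grid edges (no wrap-around).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .recordings import COMMANDS

HIGHLIGHTS = ("red", "green", "yellow")
MODES = ("comm_board", "functional")

#: Grid position of the TV icon in the functional-control layout.
DEFAULT_TV_ICON = (1, 2)


@dataclass(frozen=True)
class BoardState:
    """Immutable snapshot of the board / functional application."""

    rows: int = 4
    cols: int = 8
    cursor: tuple[int, int] = (0, 0)
    highlight: str = "red"
    mode: str = "comm_board"
    selected: bool = False
    activation_counter: int = 0  # consecutive enters before activation
    activated: bool = True  # comm_board starts active; functional does not
    tv_icon: tuple[int, int] = DEFAULT_TV_ICON
    tv_control: bool = False

    def __post_init__(self) -> None:
        r, c = self.cursor
        if not (0 <= r < self.rows and 0 <= c < self.cols):
            raise ValueError("cursor outside the grid")
        if self.highlight not in HIGHLIGHTS:
            raise ValueError(f"unknown highlight {self.highlight!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.selected != (self.highlight == "green"):
            raise ValueError("selected flag must mirror a green highlight")


def initial_state(mode: str = "comm_board",
                  cursor: tuple[int, int] = (0, 0)) -> BoardState:
    return BoardState(mode=mode, cursor=cursor,
                      activated=(mode == "comm_board"),
                      activation_counter=0)


def apply_enter_back_rule(
    previous_effective: str | None, current: str, mode: str = "comm_board",
) -> str:
    """Map a decoded command to its effective command.

    In comm_board mode a command following an enter is only valid if it is
    back; any other command is considered to be back.  In functional mode
    the rule is disabled.
    """
    if current not in COMMANDS:
        raise ValueError(f"unknown command {current!r}")
    if previous_effective is not None and previous_effective not in COMMANDS:
        raise ValueError(f"unknown command {previous_effective!r}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "comm_board" and previous_effective == "enter" and current != "back":
        return "back"
    return current


_MOVES = {"up": (-1, 0), "down": (1, 0), "left": (0, -1), "right": (0, 1)}


def board_step(state: BoardState, effective: str) -> BoardState:
    """Advance the board by one effective command (total over all commands)."""
    if effective not in COMMANDS:
        raise ValueError(f"unknown command {effective!r}")
    if effective in _MOVES:
        dr, dc = _MOVES[effective]
        r = min(max(state.cursor[0] + dr, 0), state.rows - 1)
        c = min(max(state.cursor[1] + dc, 0), state.cols - 1)
        return replace(state, cursor=(r, c), highlight="red", selected=False)
    if effective == "enter":
        return replace(state, highlight="green", selected=True)
    # back: yellow highlight replaces any existing highlight, cursor unchanged
    return replace(state, highlight="yellow", selected=False)


def functional_session_step(
    state: BoardState, effective: str,
) -> tuple[BoardState, str | None]:
    """One functional-mode step; returns (new state, emitted action or None).

    Before activation only three consecutive enters start the session (any
    other command resets the counter).  After the TV icon has been selected,
    commands are relayed as ``tv:<command>`` actions and the board freezes.
    """
    if state.mode != "functional":
        raise ValueError("functional_session_step requires functional mode")
    if effective not in COMMANDS:
        raise ValueError(f"unknown command {effective!r}")
    if not state.activated:
        if effective == "enter":
            n = state.activation_counter + 1
            if n >= 3:
                return replace(state, activated=True, activation_counter=0), None
            return replace(state, activation_counter=n), None
        return replace(state, activation_counter=0), None
    if state.tv_control:
        return state, f"tv:{effective}"
    new = board_step(state, effective)
    if effective == "enter" and state.cursor == state.tv_icon:
        new = replace(new, tv_control=True)
        return new, "select:tv"
    return new, None


def run_commands(
    commands: Sequence[str], mode: str = "comm_board",
    start: BoardState | None = None,
) -> list[tuple[str, str, BoardState, str | None]]:
    """Drive a state machine through decoded commands, applying the
    enter->back rule; returns (raw, effective, state, action) per step."""
    state = start or initial_state(mode)
    prev_effective: str | None = None
    log: list[tuple[str, str, BoardState, str | None]] = []
    for raw in commands:
        eff = apply_enter_back_rule(prev_effective, raw, mode)
        if mode == "functional":
            state, action = functional_session_step(state, eff)
        else:
            state, action = board_step(state, eff), None
        log.append((raw, eff, state, action))
        prev_effective = eff
    return log
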