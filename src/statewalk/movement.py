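"""Behavioral states, species and Markov state-switching.

A species is a set of behavioral states plus a row-stochastic transition
matrix giving the per-step probability of switching from each state to each
other.  Each state is characterized by

* ``concentration`` — mean resultant length rho of the wrapped-normal
  turning kernel, in [0, 1]; 0 is a plain random walk (uniform headings),
  values near 1 give a strongly correlated random walk.
* ``max_step_length`` — fixed per-state maximum step, attenuated by
  landscape resistance at simulation time.  A state with step length 0 is a
  Resting state: the walker stays put.
* ``perceptual_range`` — radius within which the walker perceives the
  landscape; scope of the radial resistance sampling.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MovementState",
    "TransitionMatrix",
    "Species",
    "state_rw",
    "state_crw",
    "state_resting",
    "make_transition_matrix",
    "draw_next_state",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MovementState:
    concentration: float
    max_step_length: float
    perceptual_range: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.concentration <= 1.0:
            raise ValueError(f"concentration must be in [0, 1], got {self.concentration}")
        if self.max_step_length < 0:
            raise ValueError(f"max_step_length must be >= 0, got {self.max_step_length}")
        if not self.perceptual_range > 0:
            raise ValueError(f"perceptual_range must be > 0, got {self.perceptual_range}")

    @property
    def is_resting(self) -> bool:
        return self.max_step_length == 0.0


def state_rw(step_length: float, perceptual_range: float, label: str = "RW") -> MovementState:
    """Random-walk state: uniform turning kernel (concentration 0)."""
    return MovementState(0.0, step_length, perceptual_range, label)


def state_crw(
    concentration: float, step_length: float, perceptual_range: float, label: str = "CRW"
) -> MovementState:
    """Correlated-random-walk state with the given turning-angle concentration."""
    return MovementState(concentration, step_length, perceptual_range, label)


def state_resting(perceptual_range: float, label: str = "Resting") -> MovementState:
    """Resting state: zero step length, position unchanged while occupied."""
    return MovementState(0.0, 0.0, perceptual_range, label)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic per-step state-switching probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise ValueError("transition matrix must be square")
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("transition probabilities must be in [0, 1]")
        rows = probs.sum(axis=1)
        if not np.allclose(rows, 1.0, rtol=0, atol=_ROW_SUM_TOL):
            raise ValueError(f"transition-matrix rows must sum to 1, got {rows}")
        object.__setattr__(self, "probs", probs)

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return np.array_equal(self.probs, other.probs)


def make_transition_matrix(off_diagonal_probs) -> TransitionMatrix:
    """Build a transition matrix from switching probabilities only.

    ``off_diagonal_probs`` is an S x S array whose off-diagonal entry (i, j)
    is the probability of switching from state i to state j; diagonal
    entries are ignored and filled so every row sums to 1.

    >>> make_transition_matrix([[0, 0.01], [0.01, 0]]).probs
    array([[0.99, 0.01],
           [0.01, 0.99]])
    """
    off = np.asarray(off_diagonal_probs, dtype=np.float64)
    if off.ndim != 2 or off.shape[0] != off.shape[1]:
        raise ValueError("off_diagonal_probs must be a square matrix")
    if (off < 0).any():
        raise ValueError("switching probabilities must be >= 0")
    probs = off.copy()
    np.fill_diagonal(probs, 0.0)
    off_sums = probs.sum(axis=1)
    if (off_sums > 1.0 + _ROW_SUM_TOL).any():
        bad = int(np.argmax(off_sums))
        raise ValueError(
            f"row {bad}: off-diagonal switching probabilities sum to {off_sums[bad]:g} > 1"
        )
    np.fill_diagonal(probs, 1.0 - np.minimum(off_sums, 1.0))
    return TransitionMatrix(probs)


def draw_next_state(current: int, transitions: TransitionMatrix, rng: np.random.Generator) -> int:
    """Draw the next behavioral state from the row of the current one."""
    row = transitions.probs[current]
    u = rng.random()
    # sequential CDF scan, identical to the arithmetic of the simulation core
    acc = 0.0
    for j in range(row.shape[0] - 1):
        acc += row[j]
        if u < acc:
            return j
    return row.shape[0] - 1


@dataclass(frozen=True)
class Species:
    """A named set of movement states plus their transition matrix."""

    states: tuple[MovementState, ...]
    transitions: TransitionMatrix
    name: str = "species"

    def __post_init__(self) -> None:
        states = tuple(self.states)
        if len(states) < 1:
            raise ValueError("a species needs at least one state")
        if self.transitions.n_states != len(states):
            raise ValueError(
                f"transition matrix is {self.transitions.n_states}x"
                f"{self.transitions.n_states} but species has {len(states)} states"
            )
        object.__setattr__(self, "states", states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    # -- config serialization (key-value text, used by the CLI) ----------

    def to_config(self, path: str | Path | None = None) -> str:
        cp = configparser.ConfigParser()
        cp["species"] = {"name": self.name, "n_states": str(self.n_states)}
        for i, st in enumerate(self.states):
            cp[f"state{i}"] = {
                "label": st.label,
                "concentration": repr(st.concentration),
                "max_step_length": repr(st.max_step_length),
                "perceptual_range": repr(st.perceptual_range),
            }
        cp["transitions"] = {
            f"row{i}": " ".join(repr(float(v)) for v in self.transitions.probs[i])
            for i in range(self.n_states)
        }
        buf = io.StringIO()
        cp.write(buf)
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_config(cls, source: str | Path) -> "Species":
        cp = configparser.ConfigParser()
        text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
        cp.read_string(text)
        n = cp.getint("species", "n_states")
        states = []
        for i in range(n):
            sec = cp[f"state{i}"]
            states.append(
                MovementState(
                    concentration=sec.getfloat("concentration"),
                    max_step_length=sec.getfloat("max_step_length"),
                    perceptual_range=sec.getfloat("perceptual_range"),
                    label=sec.get("label", ""),
                )
            )
        probs = np.array(
            [[float(v) for v in cp.get("transitions", f"row{i}").split()] for i in range(n)]
        )
        return cls(tuple(states), TransitionMatrix(probs), name=cp.get("species", "name"))
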