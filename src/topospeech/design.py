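"""Constrained session plans and the training/test session runners.

A session presents every grid cell an equal number of times (three in
training, ten in the 90-trial test) in randomized order, under the
constraint that no word token ever appears twice at the same location —
this breaks any association between specific words and specific cells.
Training replays a trial after every incorrect response until it is
answered correctly; in the test each stimulus may be heard at most
twice and no feedback is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Cell, GridSpec
from .encoder import TrialSpec, WordToken

__all__ = [
    "Phase",
    "Condition",
    "TRIALS_PER_CELL",
    "WordPool",
    "SessionPlan",
    "ResponseRecord",
    "SessionLog",
    "PlanInfeasibleError",
    "SessionAbortedError",
    "Violation",
    "generate_plan",
    "validate_plan",
    "run_session",
    "log_to_frame",
    "log_from_frame",
]

Phase = Literal["training", "test"]
Condition = Literal["forward", "backward"]

#: presentations of each grid cell per phase (27 and 90 trials on a 3x3 grid)
TRIALS_PER_CELL: dict[str, int] = {"training": 3, "test": 10}

LOG_COLUMNS = [
    "subject_id", "condition", "phase", "trial_index", "word_id",
    "true_row", "true_col", "resp_row", "resp_col", "n_presentations", "correct",
]


class PlanInfeasibleError(ValueError):
    """The word pool cannot satisfy the plan constraints."""


class SessionAbortedError(RuntimeError):
    """A responder raised mid-session; carries the partial log."""

    def __init__(self, message: str, partial_log: "SessionLog"):
        super().__init__(message)
        self.partial_log = partial_log


@dataclass(frozen=True)
class WordPool:
    phase: Phase
    tokens: tuple[WordToken, ...]

    def __post_init__(self) -> None:
        ids = [t.token_id for t in self.tokens]
        if len(set(ids)) != len(ids):
            raise ValueError("token_ids must be unique within a pool")
        if self.phase == "test" and any(t.bias_flag != "none" for t in self.tokens):
            raise ValueError("test pools admit only spatially unbiased tokens")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class SessionPlan:
    phase: Phase
    condition: Condition
    trials: tuple[TrialSpec, ...]
    seed: int
    grid: GridSpec


@dataclass(frozen=True)
class ResponseRecord:
    trial_index: int
    spec: TrialSpec
    response: Cell
    n_presentations: int
    correct: bool


@dataclass
class SessionLog:
    subject_id: str
    condition: Condition
    phase: Phase
    records: list[ResponseRecord] = field(default_factory=list)
    plan_seed: int = 0
    aborted: bool = False

    def __len__(self) -> int:
        return len(self.records)

    @property
    def success_rate(self) -> float:
        """Fraction of correct trials."""
        if not self.records:
            raise ValueError("empty log")
        return float(np.mean([r.correct for r in self.records]))


def generate_plan(
    phase: Phase,
    pool: WordPool,
    grid: GridSpec = GridSpec(),
    seed: int = 0,
    condition: Condition = "forward",
    reps_per_cell: int | None = None,
) -> SessionPlan:
    """Randomized session plan under the repetition constraints.

    Every cell appears exactly ``reps_per_cell`` times (3 in training,
    10 in test) in shuffled order, and no ``(token, cell)`` pair occurs
    twice.  Deterministic in ``(pool, grid, seed)``.
    """
    reps = TRIALS_PER_CELL[phase] if reps_per_cell is None else reps_per_cell
    if len(pool) < reps:
        raise PlanInfeasibleError(
            f"each cell needs {reps} distinct tokens but the pool has only "
            f"{len(pool)}: a token may appear at most once per location"
        )
    rng = np.random.default_rng(seed)
    cells = [
        Cell(r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)
    ] * reps
    order = rng.permutation(len(cells))
    used: dict[Cell, set[str]] = {}
    trials: list[TrialSpec] = []
    for i in order:
        cell = cells[i]
        taken = used.setdefault(cell, set())
        candidates = [t for t in pool.tokens if t.token_id not in taken]
        token = candidates[int(rng.integers(len(candidates)))]
        taken.add(token.token_id)
        trials.append(TrialSpec(word=token, cell=cell, condition=condition, phase=phase))
    return SessionPlan(phase=phase, condition=condition, trials=tuple(trials), seed=seed, grid=grid)


@dataclass(frozen=True)
class Violation:
    rule: str
    trial_indices: tuple[int, ...]
    message: str


def validate_plan(plan: SessionPlan, reps_per_cell: int | None = None) -> list[Violation]:
    """All constraint violations in a plan (empty list = valid)."""
    reps = TRIALS_PER_CELL[plan.phase] if reps_per_cell is None else reps_per_cell
    violations: list[Violation] = []
    expected = plan.grid.n_cells * reps
    if len(plan.trials) != expected:
        violations.append(Violation(
            "trial count", tuple(),
            f"{plan.phase} plan has {len(plan.trials)} trials, expected {expected}",
        ))
    counts: dict[Cell, list[int]] = {}
    pairs: dict[tuple[str, Cell], list[int]] = {}
    for i, t in enumerate(plan.trials):
        if not (0 <= t.cell.row < plan.grid.n_rows and 0 <= t.cell.col < plan.grid.n_cols):
            violations.append(Violation("cell bounds", (i,), f"trial {i} cell {t.cell} outside grid"))
            continue
        counts.setdefault(t.cell, []).append(i)
        pairs.setdefault((t.word.token_id, t.cell), []).append(i)
    for r in range(plan.grid.n_rows):
        for c in range(plan.grid.n_cols):
            idx = counts.get(Cell(r, c), [])
            if len(idx) != reps:
                violations.append(Violation(
                    "cell count", tuple(idx),
                    f"cell ({r},{c}) appears {len(idx)} times, expected {reps}",
                ))
    for (tok, cell), idx in pairs.items():
        if len(idx) > 1:
            violations.append(Violation(
                "word-location repeat", tuple(idx),
                f"token {tok!r} appears {len(idx)} times at cell ({cell.row},{cell.col})",
            ))
    return violations


Responder = Callable[[TrialSpec, int], Optional[Cell]]


def run_session(
    plan: SessionPlan,
    responder: Responder,
    subject_id: str = "s01",
    max_replays: int = 10,
    feedback: Callable[[TrialSpec, Cell], None] | None = None,
) -> SessionLog:
    """Run a session plan against a responder callback.

    The responder is called as ``responder(spec, presentation_count)``
    and returns the :class:`Cell` it commits to, or ``None`` to ask for
    another listen.  Training: unlimited voluntary listens; after an
    incorrect response the trial replays (with ``feedback(spec,
    correct_cell)`` delivered, when given) until answered correctly or
    ``max_replays`` total presentations, after which the trial is
    recorded incorrect and the session advances.  Test: at most two
    presentations, no feedback; a replay request on the second
    presentation is denied and the responder is re-asked to commit.
    """
    log = SessionLog(subject_id=subject_id, condition=plan.condition,
                     phase=plan.phase, plan_seed=plan.seed)
    for i, spec in enumerate(plan.trials):
        presentations = 0
        last_response: Cell | None = None
        try:
            while True:
                presentations += 1
                response = responder(spec, presentations)
                if response is None:
                    if plan.phase == "test" and presentations >= 2:
                        # third listen denied: force a committed response
                        response = responder(spec, presentations)
                        if response is None:
                            raise RuntimeError("test responder refused to commit a response")
                    else:
                        continue
                last_response = response
                correct = response == spec.cell
                if plan.phase == "training" and not correct and presentations < max_replays:
                    if feedback is not None:
                        feedback(spec, spec.cell)
                    continue
                if plan.phase == "test" and not correct and presentations < 2:
                    # the committed first response stands; no replay on error
                    pass
                break
        except Exception as exc:  # noqa: BLE001 - partial log must survive
            log.aborted = True
            raise SessionAbortedError(
                f"responder failed on trial {i}: {exc}", log
            ) from exc
        log.records.append(ResponseRecord(
            trial_index=i, spec=spec, response=last_response,
            n_presentations=presentations, correct=last_response == spec.cell,
        ))
    return log


def log_to_frame(log: SessionLog) -> pd.DataFrame:
    rows = [
        {
            "subject_id": log.subject_id, "condition": log.condition, "phase": log.phase,
            "trial_index": r.trial_index, "word_id": r.spec.word.token_id,
            "true_row": r.spec.cell.row, "true_col": r.spec.cell.col,
            "resp_row": r.response.row, "resp_col": r.response.col,
            "n_presentations": r.n_presentations, "correct": int(r.correct),
        }
        for r in log.records
    ]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def log_from_frame(df: pd.DataFrame) -> SessionLog:
    if df.empty:
        raise ValueError("empty session log frame")
    first = df.iloc[0]
    log = SessionLog(subject_id=str(first["subject_id"]),
                     condition=str(first["condition"]), phase=str(first["phase"]))
    for _, row in df.iterrows():
        spec = TrialSpec(
            word=WordToken(token_id=str(row["word_id"])),
            cell=Cell(int(row["true_row"]), int(row["true_col"])),
            condition=log.condition, phase=log.phase,
        )
        log.records.append(ResponseRecord(
            trial_index=int(row["trial_index"]), spec=spec,
            response=Cell(int(row["resp_row"]), int(row["resp_col"])),
            n_presentations=int(row["n_presentations"]),
            correct=bool(row["correct"]),
        ))
    return log
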