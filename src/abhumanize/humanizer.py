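"""Greedy framework humanization.

Repeatedly applies the single framework substitution that most increases the
humanness score until a target score is reached, the score plateaus, or an
iteration cap is hit. CDR positions and an immutable set (conserved cysteines
23/104 by default) are never touched; a negative-control mode humanizes
against the lowest-scoring model instead of the matched one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Protocol, Sequence

import numpy as np

from .ab_sequence import (
    ALPHABET,
    AMINO_ACIDS,
    GAP,
    Chain,
    ImgtPosition,
    NumberedSequence,
    encode,
    is_framework,
)

__all__ = [
    "HumanizationConfig",
    "MutationStep",
    "Trajectory",
    "StopReason",
    "enumerate_mutants",
    "humanize",
    "negative_control_humanize",
]

_N_STATES = len(ALPHABET)
_AA_OFFSET = {aa: i for i, aa in enumerate(ALPHABET)}

DEFAULT_IMMUTABLE = frozenset({ImgtPosition(23), ImgtPosition(104)})


class Scorer(Protocol):
    chain: Chain

    def score(self, seq: NumberedSequence) -> float: ...


class StopReason(str, Enum):
    TARGET_REACHED = "target_reached"
    PLATEAU = "plateau"
    MAX_ITERATIONS = "max_iterations"


@dataclass(frozen=True)
class HumanizationConfig:
    target: Optional[float] = None  # None -> the model's calibrated threshold
    max_iterations: int = 100
    immutable: frozenset[ImgtPosition] = DEFAULT_IMMUTABLE
    allow_revisit: bool = True

    def __post_init__(self) -> None:
        if self.target is not None and not 0.0 < self.target <= 1.0:
            raise ValueError(f"target score must be in (0,1], got {self.target}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for pos in self.immutable:
            if not is_framework(pos):
                raise ValueError(f"immutable positions must be framework positions, got {pos}")


@dataclass(frozen=True)
class MutationStep:
    position: ImgtPosition
    from_residue: str
    to_residue: str
    score_before: float
    score_after: float

    def __post_init__(self) -> None:
        if not is_framework(self.position):
            raise ValueError(f"mutation outside framework: {self.position}")
        if self.from_residue == self.to_residue:
            raise ValueError("from and to residues must differ")
        if not self.score_after > self.score_before:
            raise ValueError("accepted steps must strictly increase the score")


@dataclass
class Trajectory:
    input_sequence: NumberedSequence
    steps: list[MutationStep]
    final_sequence: NumberedSequence
    reached_target: bool
    stop_reason: StopReason
    initial_score: float
    final_score: float

    def replay(self) -> NumberedSequence:
        """Re-apply the recorded steps to the input sequence."""
        seq = self.input_sequence
        for step in self.steps:
            if seq.residue_at(step.position) != step.from_residue:
                raise ValueError(f"trajectory inconsistent at {step.position}")
            seq = seq.with_substitution(step.position, step.to_residue)
        return seq


def _mutable_positions(seq: NumberedSequence, config: HumanizationConfig) -> list[ImgtPosition]:
    return [p for p in seq.framework_positions() if p not in config.immutable]


def enumerate_mutants(
    seq: NumberedSequence, config: HumanizationConfig = HumanizationConfig()
) -> list[tuple[ImgtPosition, str, NumberedSequence]]:
    """All single-site framework substitutions: |mutable positions| x 19
    mutants, in (ascending position, alphabetical residue) order."""
    mutable = _mutable_positions(seq, config)
    if not mutable:
        raise ValueError(f"sequence {seq.id!r} has no mutable framework positions")
    out = []
    for pos in mutable:
        current = seq.residues[pos]
        for aa in AMINO_ACIDS:
            if aa == current:
                continue
            out.append((pos, aa, seq.with_substitution(pos, aa)))
    return out


def _score_mutants(
    scorer, seq: NumberedSequence, mutable: Sequence[ImgtPosition]
) -> tuple[list[tuple[ImgtPosition, str]], np.ndarray]:
    """Scores for every (position, to_residue) candidate, in tie-break order.

    Uses a vectorized one-hot edit when the scorer exposes ``score_vectors`` +
    ``universe`` (the trained-forest fast path); otherwise falls back to
    scoring mutant sequences one by one.
    """
    candidates = [
        (pos, aa)
        for pos in mutable
        for aa in AMINO_ACIDS
        if aa != seq.residues[pos]
    ]
    if hasattr(scorer, "score_vectors") and hasattr(scorer, "universe"):
        uindex = {p: i for i, p in enumerate(scorer.universe)}
        base = encode(seq, scorer.universe)
        X = np.tile(base, (len(candidates), 1))
        for row, (pos, aa) in enumerate(candidates):
            i = uindex.get(pos)
            if i is None:
                continue  # position excluded from model universe: no-op mutant
            block = i * _N_STATES
            X[row, block + _AA_OFFSET[seq.residues[pos]]] = 0.0
            X[row, block + _AA_OFFSET[aa]] = 1.0
        scores = scorer.score_vectors(X)
    else:
        scores = np.array([scorer.score(seq.with_substitution(pos, aa)) for pos, aa in candidates])
    return candidates, scores


def humanize(
    seq: NumberedSequence,
    model: Scorer,
    config: HumanizationConfig = HumanizationConfig(),
) -> Trajectory:
    """Greedy humanization loop.

    At each iteration every single-site framework mutant is scored and the
    strict-maximum improvement is applied (ties broken by lowest IMGT
    position, then alphabetical target residue). Stops when the score reaches
    the target, no mutant strictly improves it (plateau), or at the iteration
    cap. Deterministic for a fixed model and config.
    """
    if getattr(model, "chain", seq.chain) != seq.chain:
        raise ValueError(
            f"chain mismatch: model is {model.chain.value}, sequence {seq.id!r} is {seq.chain.value}"
        )
    target = config.target
    if target is None:
        target = getattr(model, "threshold", None)
        if target is None:
            raise ValueError("no target score given and model has no calibrated threshold")

    current = seq
    current_score = float(model.score(seq))
    initial_score = current_score
    steps: list[MutationStep] = []
    visited: set[ImgtPosition] = set()

    def finish(reason: StopReason) -> Trajectory:
        return Trajectory(
            input_sequence=seq,
            steps=steps,
            final_sequence=current,
            reached_target=current_score >= target,
            stop_reason=reason,
            initial_score=initial_score,
            final_score=current_score,
        )

    if current_score >= target:
        return finish(StopReason.TARGET_REACHED)

    for _ in range(config.max_iterations):
        mutable = _mutable_positions(current, config)
        if not config.allow_revisit:
            mutable = [p for p in mutable if p not in visited]
        if not mutable:
            return finish(StopReason.PLATEAU)
        candidates, scores = _score_mutants(model, current, mutable)
        best = int(np.argmax(scores))  # argmax keeps the first (tie-break) order
        best_score = float(scores[best])
        if best_score <= current_score:
            return finish(StopReason.PLATEAU)
        pos, aa = candidates[best]
        steps.append(
            MutationStep(
                position=pos,
                from_residue=current.residues[pos],
                to_residue=aa,
                score_before=current_score,
                score_after=best_score,
            )
        )
        current = current.with_substitution(pos, aa)
        visited.add(pos)
        current_score = best_score
        if current_score >= target:
            return finish(StopReason.TARGET_REACHED)
    return finish(StopReason.MAX_ITERATIONS)


def negative_control_humanize(
    seq: NumberedSequence,
    models: Sequence[Scorer],
    config: HumanizationConfig = HumanizationConfig(),
    seed: int = 0,
) -> tuple[Trajectory, Scorer]:
    """Humanize against the lowest-scoring model (wrong-V-gene control).

    Exact score ties are resolved by a seeded uniform choice.
    """
    matching = [m for m in models if m.chain == seq.chain]
    if len(matching) < 2:
        raise ValueError("negative control requires at least two models of the sequence's chain")
    scores = np.array([m.score(seq) for m in matching])
    lowest = np.flatnonzero(scores == scores.min())
    rng = np.random.default_rng(seed)
    chosen = matching[int(rng.choice(lowest))]
    return humanize(seq, chosen, config), chosen
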