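"""Comparison metrics between tool-suggested and experimental humanization.

Mutation-set extraction, overlap ratio (OR), adjusted overlap ratio (AOR,
counting same-similarity-group substitutions as matches), mutation ratio,
panel aggregation, a random-humanization Monte-Carlo baseline, positional
category accounting, and ADA-score correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ab_sequence import (
    AMINO_ACIDS,
    Chain,
    ImgtPosition,
    NumberedSequence,
    is_framework,
)

__all__ = [
    "MutationSet",
    "OverlapReport",
    "AdaRecord",
    "DEFAULT_SIMILARITY_GROUPS",
    "DEFAULT_INTERFACE_POSITIONS",
    "DEFAULT_VERNIER_POSITIONS",
    "round_half_up",
    "diff_sequences",
    "overlap_ratio",
    "adjusted_overlap_ratio",
    "mutation_ratio",
    "overlap_report",
    "aggregate",
    "random_baseline",
    "ada_correlation",
    "positional_category_stats",
    "load_reference_panel",
    "reference_panel_summary",
]

#: Default amino-acid similarity grouping for the adjusted overlap ratio
#: (overridable; any partition of the 20 amino acids is accepted).
DEFAULT_SIMILARITY_GROUPS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIM"),
    "aromatic": frozenset("FWY"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQC"),
    "special": frozenset("GP"),
}

#: Editable default framework position categories (IMGT codes). Stand-ins for
#: the usual VH-VL interface and Vernier-zone residue lists.
DEFAULT_INTERFACE_POSITIONS: frozenset[ImgtPosition] = frozenset(
    ImgtPosition(n) for n in (39, 41, 42, 44, 45, 46, 47, 49, 50, 118, 120, 121, 124)
)
DEFAULT_VERNIER_POSITIONS: frozenset[ImgtPosition] = frozenset(
    ImgtPosition(n) for n in (2, 25, 26, 40, 53, 55, 66, 67, 68, 69, 76, 78, 80, 82, 87, 94, 118)
)


def _validate_groups(groups: Mapping[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    union: set[str] = set()
    for name, members in groups.items():
        if union & set(members):
            raise ValueError(f"similarity groups must be disjoint; overlap at group {name!r}")
        union |= set(members)
    if union != set(AMINO_ACIDS):
        raise ValueError("similarity groups must partition the 20 standard amino acids")
    return {k: frozenset(v) for k, v in groups.items()}


def _group_of(aa: str, groups: Mapping[str, frozenset[str]]) -> str:
    for name, members in groups.items():
        if aa in members:
            return name
    raise ValueError(f"residue {aa!r} not covered by similarity groups")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounding up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MutationSet:
    """Final-state framework substitutions for one chain: at most one entry
    per position, from precursor residue to final residue."""

    entries: frozenset[tuple[ImgtPosition, str, str]]
    chain: Chain
    sequence_id: str = ""

    def __post_init__(self) -> None:
        positions = [e[0] for e in self.entries]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one mutation per position (final-state semantics)")
        for pos, frm, to in self.entries:
            if not is_framework(pos):
                raise ValueError(f"mutation outside framework: {pos}")
            if frm == to:
                raise ValueError(f"null mutation at {pos}")

    def __len__(self) -> int:
        return len(self.entries)

    def by_position(self) -> dict[ImgtPosition, tuple[str, str]]:
        return {pos: (frm, to) for pos, frm, to in self.entries}


@dataclass(frozen=True)
class OverlapReport:
    n_tool: int
    n_exp: int
    overlap_pct: int
    adjusted_overlap_pct: int
    mutation_ratio_pct: int

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_pct <= self.adjusted_overlap_pct <= 100:
            raise ValueError("requires 0 <= OR <= AOR <= 100")
        if self.mutation_ratio_pct < 0:
            raise ValueError("mutation ratio must be non-negative")


@dataclass(frozen=True)
class AdaRecord:
    therapeutic_id: str
    ada_percent: float  # % of patients developing anti-drug antibodies
    min_chain_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ada_percent <= 100.0:
            raise ValueError("ADA percent must be in [0,100]")
        if not 0.0 <= self.min_chain_score <= 1.0:
            raise ValueError("humanness score must be in [0,1]")


# --------------------------------------------------------------------------
# Mutation sets and ratios
# --------------------------------------------------------------------------

def diff_sequences(precursor: NumberedSequence, final: NumberedSequence) -> MutationSet:
    """Framework positions where the final sequence differs from the precursor."""
    if precursor.chain != final.chain:
        raise ValueError("precursor and final must share a chain")
    if set(precursor.positions) != set(final.positions):
        raise ValueError(
            f"position sets differ between {precursor.id!r} and {final.id!r} (substitution-only semantics)"
        )
    entries = {
        (pos, precursor.residues[pos], final.residues[pos])
        for pos in precursor.positions
        if is_framework(pos) and precursor.residues[pos] != final.residues[pos]
    }
    return MutationSet(entries=frozenset(entries), chain=precursor.chain, sequence_id=precursor.id)


def _matches(
    tool: MutationSet,
    exp: MutationSet,
    groups: Optional[Mapping[str, frozenset[str]]],
) -> int:
    exp_by_pos = exp.by_position()
    n = 0
    for pos, _, to in tool.entries:
        if pos not in exp_by_pos:
            continue
        exp_to = exp_by_pos[pos][1]
        if to == exp_to:
            n += 1
        elif groups is not None and _group_of(to, groups) == _group_of(exp_to, groups):
            n += 1
    return n


def overlap_ratio(tool: MutationSet, exp: MutationSet) -> int:
    """Percent of tool mutations also made experimentally (same position AND
    same target residue), rounded half-up."""
    if len(tool) == 0:
        raise ValueError("overlap ratio undefined for an empty tool mutation set")
    return round_half_up(100.0 * _matches(tool, exp, None) / len(tool))


def adjusted_overlap_ratio(
    tool: MutationSet,
    exp: MutationSet,
    groups: Mapping[str, frozenset[str]] = DEFAULT_SIMILARITY_GROUPS,
) -> int:
    """Overlap ratio also counting target residues in the same similarity group."""
    if len(tool) == 0:
        raise ValueError("adjusted overlap ratio undefined for an empty tool mutation set")
    groups = _validate_groups(groups)
    return round_half_up(100.0 * _matches(tool, exp, groups) / len(tool))


def mutation_ratio(tool: MutationSet, exp: MutationSet) -> int:
    """Tool mutation count as a percent of the experimental count, half-up."""
    if len(exp) == 0:
        raise ValueError("mutation ratio undefined for an empty experimental set")
    return round_half_up(100.0 * len(tool) / len(exp))


def overlap_report(
    tool: MutationSet,
    exp: MutationSet,
    groups: Mapping[str, frozenset[str]] = DEFAULT_SIMILARITY_GROUPS,
) -> OverlapReport:
    return OverlapReport(
        n_tool=len(tool),
        n_exp=len(exp),
        overlap_pct=overlap_ratio(tool, exp),
        adjusted_overlap_pct=adjusted_overlap_ratio(tool, exp, groups),
        mutation_ratio_pct=mutation_ratio(tool, exp),
    )


def aggregate(reports: Sequence[OverlapReport]) -> dict[str, dict[str, int]]:
    """Mean and median of each metric over a panel, rounded half-up."""
    if not reports:
        raise ValueError("aggregate requires at least one report")
    cols = {
        "overlap_pct": [r.overlap_pct for r in reports],
        "adjusted_overlap_pct": [r.adjusted_overlap_pct for r in reports],
        "mutation_ratio_pct": [r.mutation_ratio_pct for r in reports],
    }
    return {
        name: {
            "mean": round_half_up(float(np.mean(vals))),
            "median": round_half_up(float(np.median(vals))),
        }
        for name, vals in cols.items()
    }


# --------------------------------------------------------------------------
# Random-humanization baseline
# --------------------------------------------------------------------------

def random_baseline(
    exp: MutationSet,
    mutable: Mapping[ImgtPosition, str],
    n_tool: int,
    groups: Mapping[str, frozenset[str]] = DEFAULT_SIMILARITY_GROUPS,
    reps: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Expected OR/AOR of a random humanizer.

    Each replicate draws ``n_tool`` substitutions uniformly over
    (mutable position x 19 non-identical residues) without position reuse,
    scores them against ``exp`` and averages. Returns means and Monte-Carlo
    standard errors (of unrounded percentages).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    positions = sorted(mutable, key=ImgtPosition.sort_key)
    if n_tool > len(positions):
        raise ValueError("n_tool exceeds the number of mutable positions")
    if n_tool < 1:
        raise ValueError("n_tool must be >= 1")
    groups = _validate_groups(groups)
    exp_by_pos = exp.by_position()
    rng = np.random.default_rng(seed)
    ors = np.empty(reps)
    aors = np.empty(reps)
    alternatives = {pos: [aa for aa in AMINO_ACIDS if aa != frm] for pos, frm in mutable.items()}
    for r in range(reps):
        chosen = rng.choice(len(positions), size=n_tool, replace=False)
        n_or = 0
        n_aor = 0
        for idx in chosen:
            pos = positions[idx]
            to = alternatives[pos][rng.integers(19)]
            if pos in exp_by_pos:
                exp_to = exp_by_pos[pos][1]
                if to == exp_to:
                    n_or += 1
                    n_aor += 1
                elif _group_of(to, groups) == _group_of(exp_to, groups):
                    n_aor += 1
        ors[r] = 100.0 * n_or / n_tool
        aors[r] = 100.0 * n_aor / n_tool
    return {
        "or_mean": float(ors.mean()),
        "or_se": float(ors.std(ddof=1) / math.sqrt(reps)) if reps > 1 else float("nan"),
        "aor_mean": float(aors.mean()),
        "aor_se": float(aors.std(ddof=1) / math.sqrt(reps)) if reps > 1 else float("nan"),
    }


# --------------------------------------------------------------------------
# ADA correlation
# --------------------------------------------------------------------------

def ada_correlation(records: Sequence[AdaRecord]) -> float:
    """R-squared of the OLS regression of ADA percent on minimum chain score."""
    if len(records) < 3:
        raise ValueError("ADA correlation requires at least 3 records")
    x = np.array([r.min_chain_score for r in records])
    y = np.array([r.ada_percent for r in records])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: scores or ADA values are constant")
    from scipy.stats import linregress

    return float(linregress(x, y).rvalue ** 2)


# --------------------------------------------------------------------------
# Positional category accounting
# --------------------------------------------------------------------------

def positional_category_stats(
    tool_sets: Sequence[MutationSet],
    category: frozenset[ImgtPosition],
    exp_sets: Optional[Sequence[MutationSet]] = None,
) -> dict:
    """Per-sequence counts of mutations in a framework position category
    (e.g. VH-VL interface or Vernier zone), their mean, and — when paired
    experimental sets are supplied — the category-restricted overlap ratio."""
    if not category:
        raise ValueError("category must be non-empty")
    for pos in category:
        if not is_framework(pos):
            raise ValueError(f"category positions must be framework positions: {pos}")
    counts = [sum(1 for pos, _, _ in ms.entries if pos in category) for ms in tool_sets]
    result: dict = {
        "counts": counts,
        "mean_count": float(np.mean(counts)) if counts else 0.0,
    }
    if exp_sets is not None:
        if len(exp_sets) != len(tool_sets):
            raise ValueError("tool and experimental set lists must pair up")
        n_cat_tool = 0
        n_cat_match = 0
        for tool, exp in zip(tool_sets, exp_sets):
            exp_by_pos = exp.by_position()
            for pos, _, to in tool.entries:
                if pos not in category:
                    continue
                n_cat_tool += 1
                if pos in exp_by_pos and exp_by_pos[pos][1] == to:
                    n_cat_match += 1
        result["category_overlap_pct"] = (
            round_half_up(100.0 * n_cat_match / n_cat_tool) if n_cat_tool else None
        )
    return result


# --------------------------------------------------------------------------
# Bundled reference panel (25 experimentally humanized therapeutics)
# --------------------------------------------------------------------------

def load_reference_panel() -> pd.DataFrame:
    """Published per-therapeutic comparison panel: OR/AOR/mutation counts for
    the VH and VL chains of 25 experimentally humanized therapeutics."""
    with resources.files("abhumanize.data").joinpath("reference_panel.csv").open("r") as fh:
        return pd.read_csv(fh)


def reference_panel_summary(panel: Optional[pd.DataFrame] = None) -> dict[str, dict[str, int]]:
    """Aggregate the bundled panel with :func:`aggregate`, per chain."""
    if panel is None:
        panel = load_reference_panel()
    out: dict[str, dict[str, int]] = {}
    for prefix in ("vh", "vl"):
        reports = [
            OverlapReport(
                n_tool=int(row[f"{prefix}_n_tool"]),
                n_exp=int(row[f"{prefix}_n_exp"]),
                overlap_pct=int(row[f"{prefix}_overlap_pct"]),
                adjusted_overlap_pct=int(row[f"{prefix}_adjusted_overlap_pct"]),
                mutation_ratio_pct=int(row[f"{prefix}_mutation_ratio_pct"]),
            )
            for _, row in panel.iterrows()
        ]
        agg = aggregate(reports)
        for metric, stats in agg.items():
            out[f"{prefix}_{metric}"] = stats
    return out
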