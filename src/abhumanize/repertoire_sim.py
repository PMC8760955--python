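"""Synthetic labeled repertoires for training and benchmarking.

Builds germline templates per chain/species/V-gene with species-distinguishing
framework "signature" residues, then draws records by applying region-dependent
somatic-hypermutation-style substitutions. Optionally injects the QC artifacts
(duplicates arise naturally, cysteine errors, truncated FR1) that
:func:`~abhumanize.ab_sequence.quality_filter` removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .ab_sequence import (
    AMINO_ACIDS,
    Chain,
    ImgtPosition,
    NumberedSequence,
    assign_region,
    is_framework,
)

__all__ = [
    "GermlineTemplate",
    "SHMModel",
    "SimConfig",
    "SimReport",
    "make_default_germlines",
    "simulate_repertoire",
    "signature_position_numbers",
]

_AA = np.array(list(AMINO_ACIDS))
_AA_TO_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Conserved cysteines are never touched by SHM so germline-derived records
# stay structurally valid.
_CONSERVED = frozenset({ImgtPosition(23), ImgtPosition(104)})

# Framework positions eligible to carry species signatures, spread over
# FR1-FR3 and avoiding the conserved cysteines.
_SIGNATURE_CANDIDATES = (
    2, 5, 11, 20, 40, 44, 48, 68, 70, 77, 84, 93, 7, 15, 42, 50, 72, 80, 88, 97,
)


def signature_position_numbers(count: int) -> list[int]:
    """First ``count`` framework positions used as species signatures."""
    if count > len(_SIGNATURE_CANDIDATES):
        raise ValueError(f"at most {len(_SIGNATURE_CANDIDATES)} signature positions supported")
    return sorted(_SIGNATURE_CANDIDATES[:count])


@dataclass(frozen=True)
class GermlineTemplate:
    species: str
    chain: Chain
    v_gene: str
    residues: Mapping[ImgtPosition, str]

    def to_sequence(self, id: str) -> NumberedSequence:
        return NumberedSequence(
            id=id,
            chain=self.chain,
            residues=dict(self.residues),
            species=self.species,
            v_gene=self.v_gene,
            source="simulated",
        )


@dataclass
class SHMModel:
    """Per-region substitution model (substitution-only, no indels)."""

    framework_rate: float = 0.02
    cdr_rate: float = 0.08
    substitution_weights: Optional[np.ndarray] = None  # 20x20 row-stochastic, zero diagonal

    def __post_init__(self) -> None:
        for name, rate in (("framework_rate", self.framework_rate), ("cdr_rate", self.cdr_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {rate}")
        if self.substitution_weights is None:
            w = np.full((20, 20), 1.0 / 19.0)
            np.fill_diagonal(w, 0.0)
            self.substitution_weights = w
        else:
            w = np.asarray(self.substitution_weights, dtype=float)
            if w.shape != (20, 20):
                raise ValueError("substitution_weights must be 20x20")
            if np.any(np.diag(w) != 0):
                raise ValueError("substitution_weights must have zero diagonal (no self-substitution)")
            if not np.allclose(w.sum(axis=1), 1.0):
                raise ValueError("substitution_weights rows must sum to 1")
            self.substitution_weights = w

    def rate_for(self, pos: ImgtPosition) -> float:
        return self.framework_rate if is_framework(pos) else self.cdr_rate


@dataclass
class SimConfig:
    n_per_class: int = 1000
    chain: Chain = Chain.HEAVY
    species_mix: Mapping[str, float] = field(default_factory=lambda: {"mouse": 0.5, "rat": 0.5})
    signature_positions: int = 12
    seed: int = 0
    shm: SHMModel = field(default_factory=SHMModel)
    inject_qc_artifacts: bool = False
    qc_artifact_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        self.chain = Chain(self.chain)
        total = sum(self.species_mix.values())
        if total <= 0:
            raise ValueError("species_mix weights must be positive")
        self.species_mix = {k: v / total for k, v in self.species_mix.items()}


@dataclass
class SimReport:
    requested_per_class: int
    kept_positive: int
    kept_negative: int
    duplicates_removed: int
    artifacts_injected: int


# --------------------------------------------------------------------------
# Germline construction
# --------------------------------------------------------------------------

# Fixed per-chain scaffold seeds: templates are fixtures, independent of the
# user-facing simulation seed.
_CHAIN_SCAFFOLD_SEED = {Chain.HEAVY: 101, Chain.KAPPA: 202, Chain.LAMBDA: 303}

# Distinct framework positions perturbed per human V gene, so that V genes of
# the same chain are themselves distinguishable.
_VGENE_DISTINCT = {
    "V1": (3, 17, 41, 67, 85, 100),
    "V3": (8, 21, 46, 74, 90, 119),
    "V4": (13, 25, 53, 79, 94, 123),
    "KV1": (3, 17, 41, 67, 85, 100),
    "LV1": (8, 21, 46, 74, 90, 119),
}

_HUMAN_VGENES = {Chain.HEAVY: ("V1", "V3", "V4"), Chain.KAPPA: ("KV1",), Chain.LAMBDA: ("LV1",)}


def _base_scaffold(chain: Chain) -> dict[ImgtPosition, str]:
    rng = np.random.default_rng(_CHAIN_SCAFFOLD_SEED[chain])
    residues = {ImgtPosition(n): str(rng.choice(_AA)) for n in range(1, 129)}
    residues[ImgtPosition(23)] = "C"
    residues[ImgtPosition(104)] = "C"
    return residues


def _shift_residue(aa: str, offset: int) -> str:
    return AMINO_ACIDS[(_AA_TO_IDX[aa] + offset) % 20]


def make_default_germlines(signature_positions: int = 12) -> list[GermlineTemplate]:
    """Built-in germline fixture set.

    Human heavy V1/V3/V4, human kappa and lambda, plus mouse and rat
    counterparts of every human V gene. A non-human counterpart differs from
    its human V gene at exactly ``signature_positions`` framework sites
    (species-specific consensus residues) and shares the CDR grammar, so the
    signature sites are the only discriminant within a V-gene family. Human
    V genes of the same chain are distinguished by small V-gene-specific
    framework perturbations of the chain scaffold.
    """
    signatures = [ImgtPosition(n) for n in signature_position_numbers(signature_positions)]
    templates: list[GermlineTemplate] = []
    for chain, vgenes in _HUMAN_VGENES.items():
        base = _base_scaffold(chain)
        for vg in vgenes:
            res = dict(base)
            for n in _VGENE_DISTINCT[vg]:
                pos = ImgtPosition(n)
                if pos in _CONSERVED:
                    continue
                res[pos] = _shift_residue(base[pos], 3)
            templates.append(GermlineTemplate("human", chain, vg, res))
            # species consensus: a deterministic distinct residue per signature site
            for species, offset in (("mouse", 7), ("rat", 11)):
                sp_res = dict(res)
                for pos in signatures:
                    sp_res[pos] = _shift_residue(res[pos], offset)
                templates.append(GermlineTemplate(species, chain, f"{species}_{vg}", sp_res))
    return templates


# --------------------------------------------------------------------------
# Repertoire simulation
# --------------------------------------------------------------------------

def _apply_shm(
    template: GermlineTemplate, shm: SHMModel, rng: np.random.Generator
) -> dict[ImgtPosition, str]:
    residues = dict(template.residues)
    positions = [p for p in residues if p not in _CONSERVED]
    rates = np.array([shm.rate_for(p) for p in positions])
    hits = rng.random(len(positions)) < rates
    for pos, hit in zip(positions, hits):
        if not hit:
            continue
        row = shm.substitution_weights[_AA_TO_IDX[residues[pos]]]
        residues[pos] = str(rng.choice(_AA, p=row))
    return residues


def _inject_artifact(residues: dict[ImgtPosition, str], rng: np.random.Generator) -> str:
    if rng.random() < 0.5:
        residues[ImgtPosition(23)] = "A"
        return "cysteine_error"
    for n in range(1, 6):
        residues.pop(ImgtPosition(n), None)
    return "missing_fr1"


def simulate_repertoire(
    config: SimConfig,
    germlines: Optional[Sequence[GermlineTemplate]] = None,
    return_report: bool = False,
):
    """Draw a labeled repertoire: human positives per V gene plus a non-human
    species mix, with per-region SHM substitutions.

    Exact duplicate residue maps are removed (first occurrence kept). Each
    record has its own RNG stream derived from ``(seed, record index)``, so a
    fixed seed reproduces the repertoire and any subset of it.
    """
    if germlines is None:
        germlines = make_default_germlines(config.signature_positions)
    chain_templates = [t for t in germlines if t.chain == config.chain]
    human = [t for t in chain_templates if t.species == "human"]
    by_species = {
        sp: [t for t in chain_templates if t.species == sp] for sp in config.species_mix
    }
    if not human:
        raise ValueError(f"no human germline templates for chain {config.chain.value!r}")
    for sp, ts in by_species.items():
        if not ts:
            raise ValueError(f"no {sp!r} germline templates for chain {config.chain.value!r}")

    species_names = sorted(config.species_mix)
    species_probs = np.array([config.species_mix[sp] for sp in species_names])

    records: list[NumberedSequence] = []
    seen: set[tuple] = set()
    duplicates = 0
    artifacts = 0
    for i in range(2 * config.n_per_class):
        rng = np.random.default_rng([config.seed, i])
        positive = i < config.n_per_class
        if positive:
            template = human[rng.integers(len(human))]
            label = "pos"
        else:
            sp = species_names[rng.choice(len(species_names), p=species_probs)]
            pool = by_species[sp]
            template = pool[rng.integers(len(pool))]
            label = "neg"
        residues = _apply_shm(template, config.shm, rng)
        source = "simulated"
        if config.inject_qc_artifacts and rng.random() < config.qc_artifact_fraction:
            source = "simulated/" + _inject_artifact(residues, rng)
            artifacts += 1
        key = tuple(sorted(residues.items(), key=lambda kv: kv[0].sort_key()))
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        records.append(
            NumberedSequence(
                id=f"{label}_{i}",
                chain=config.chain,
                residues=residues,
                species=template.species,
                v_gene=template.v_gene,
                source=source,
            )
        )
    if return_report:
        report = SimReport(
            requested_per_class=config.n_per_class,
            kept_positive=sum(1 for r in records if r.species == "human"),
            kept_negative=sum(1 for r in records if r.species != "human"),
            duplicates_removed=duplicates,
            artifacts_injected=artifacts,
        )
        return records, report
    return records
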