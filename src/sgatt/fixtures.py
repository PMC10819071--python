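"""Synthetic SMILES datasets with known structure→label rules.

Molecules are scaffold cores decorated with functional-group branches
drawn from the default knowledge table, so fixture tasks are learnable
exactly through the features the model claims to exploit. Labels are
deterministic functions of structure: an indicator of a target group's
presence (classification) or an additive per-group score plus optional
Gaussian noise (regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .knowledge import KnowledgeBase, build_knowledge_base, match_functional_groups
from .molio import PropertyDataset, parse_smiles

#: scaffold cores as string parts; decorations are inserted between parts
DEFAULT_SCAFFOLDS: tuple[tuple[str, ...], ...] = (
    ("CC", "C", "C"),
    ("CCC", "CC", "C"),
    ("CC(C)C", "C", ""),
    ("CCOC", "C", ""),
    ("CC1C", "C1", ""),
    ("C1CC", "CC", "C1"),
    ("c1cc", "cc", "c1"),
    ("c1ccnc", "c1", ""),
    ("c1cc", "oc1", ""),
    ("CCCCC", "C", ""),
)

#: decoration branch SMILES keyed by the functional group they introduce
DEFAULT_DECORATIONS: dict[str, str] = {
    "hydroxyl": "O",
    "amino": "N",
    "methyl": "C",
    "carboxyl": "C(=O)O",
    "nitro": "[N+](=O)[O-]",
    "halogen": "Cl",
    "thiol": "S",
    "amide": "C(=O)N",
    "ester": "C(=O)OC",
}

#: additive regression contributions per functional-group occurrence
DEFAULT_GROUP_SCORES: dict[str, float] = {
    "hydroxyl": 1.0,
    "amino": 0.8,
    "methyl": -0.3,
    "carboxyl": 1.5,
    "nitro": -1.2,
    "halogen": -0.6,
    "thiol": 0.4,
    "amide": 0.9,
    "ester": 0.2,
    "carbonyl": 0.1,
    "ether": -0.1,
}


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Recipe for a synthetic labelled SMILES set."""

    n_molecules: int = 200
    task_type: str = "classification"
    target_group: str = "hydroxyl"  # classification label = presence of this group
    balance: float = 0.5  # target positive fraction (classification)
    noise_sigma: float = 0.0  # regression noise
    seed: int = 0
    scaffolds: Sequence[tuple[str, ...]] = DEFAULT_SCAFFOLDS
    decorations: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DECORATIONS))
    group_scores: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_SCORES))


def _assemble(parts: tuple[str, ...], branches: Sequence[str | None]) -> str:
    out = []
    for i, part in enumerate(parts):
        out.append(part)
        if i < len(parts) - 1:
            b = branches[i]
            if b:
                out.append(f"({b})")
    return "".join(out)


def enumerate_pool(spec: FixtureSpec) -> list[str]:
    """All distinct valid scaffold+decoration combinations (deterministic order)."""
    decos: list[str | None] = [None] + list(spec.decorations.values())
    pool: list[str] = []
    seen: set[str] = set()
    for parts in spec.scaffolds:
        n_slots = len(parts) - 1
        combos = [[d] for d in decos]
        for _ in range(n_slots - 1):
            combos = [c + [d] for c in combos for d in decos]
        for branches in combos:
            smi = _assemble(parts, branches)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            pool.append(smi)
    return pool


def _group_counts(smiles: str, kb: KnowledgeBase) -> dict[str, int]:
    graph = parse_smiles(smiles, add_hydrogens=True)
    counts: dict[str, int] = {}
    for name, _atoms in match_functional_groups(graph, kb):
        counts[name] = counts.get(name, 0) + 1
    return counts


def generate(spec: FixtureSpec, kb: KnowledgeBase | None = None) -> PropertyDataset:
    """Generate a :class:`PropertyDataset` according to the spec.

    Classification sampling is stratified towards ``spec.balance``; raises
    :class:`FixtureError` (stating the achievable maximum) when the
    enumerable pool cannot supply ``n_molecules`` distinct molecules.
    """
    if spec.task_type not in ("classification", "regression"):
        raise FixtureError(f"unknown task_type {spec.task_type!r}")
    kb = kb or build_knowledge_base()
    rng = np.random.default_rng(spec.seed)
    pool = enumerate_pool(spec)
    if len(pool) < spec.n_molecules:
        raise FixtureError(
            f"spec yields only {len(pool)} distinct molecules, fewer than {spec.n_molecules}"
        )
    counts = {smi: _group_counts(smi, kb) for smi in pool}

    if spec.task_type == "classification":
        pos = [s for s in pool if counts[s].get(spec.target_group, 0) > 0]
        neg = [s for s in pool if s not in set(pos)]
        n_pos = int(round(spec.n_molecules * spec.balance))
        n_neg = spec.n_molecules - n_pos
        if len(pos) < n_pos or len(neg) < n_neg:
            raise FixtureError(
                f"cannot reach balance {spec.balance}: pool has {len(pos)} positive "
                f"and {len(neg)} negative molecules (need {n_pos}/{n_neg})"
            )
        chosen = list(rng.choice(pos, size=n_pos, replace=False)) + list(
            rng.choice(neg, size=n_neg, replace=False)
        )
        order = rng.permutation(len(chosen))
        records = []
        for i in order:
            smi = chosen[i]
            y = 1.0 if counts[smi].get(spec.target_group, 0) > 0 else 0.0
            records.append((smi, np.array([y]), np.array([True])))
        return PropertyDataset(records=records, task_names=["label"], task_type="classification")

    chosen = list(rng.choice(pool, size=spec.n_molecules, replace=False))
    records = []
    for smi in chosen:
        score = sum(spec.group_scores.get(g, 0.0) * c for g, c in counts[smi].items())
        if spec.noise_sigma > 0:
            score += rng.normal(0.0, spec.noise_sigma)
        records.append((smi, np.array([score]), np.array([True])))
    return PropertyDataset(records=records, task_names=["target"], task_type="regression")
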