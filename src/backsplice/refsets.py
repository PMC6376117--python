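"""Matched reference (control) sets for circRNA comparisons.

Six constructions are supported: the cell-specific expressed-gene set
(mean FPKM >= 1), the non-circRNA-producing subset of it, exon-count-,
gene-length- and expression-adjusted gene sets (nearest-neighbour
matching without replacement to the circRNA genes' property values),
and position-adjusted exon/intron feature sets (largest-remainder
allocation of counts to ordinal positions, then seeded sampling within
each position). Every set is a pure function of (pool, targets, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Optional, Sequence

import numpy as np

SET_KINDS = {
    "non_circ",
    "exon_count_adjusted",
    "gene_length_adjusted",
    "cell_specific",
    "expression_adjusted",
    "position_adjusted",
}


@dataclass
class MatchedSet:
    kind: str
    members: list
    seed: Optional[int] = None
    target_mean: Optional[float] = None
    achieved_mean: Optional[float] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SET_KINDS:
            raise ValueError(f"unknown set kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def build_cell_specific(
    expression, samples: Optional[Sequence[str]] = None, threshold: float = 1.0
) -> MatchedSet:
    """Genes whose mean FPKM across the cell type's samples is >= the
    threshold (inclusive)."""
    genes = sorted(expression.expressed_genes(samples, threshold))
    return MatchedSet("cell_specific", genes, notes={"threshold": threshold})


def build_non_circ(expressed_genes, circ_genes) -> MatchedSet:
    """Expressed genes minus the circRNA-producing genes."""
    members = sorted(set(expressed_genes) - set(circ_genes))
    if not members and set(expressed_genes):
        warnings.warn("non-circ reference set is empty: every expressed "
                      "gene produces a circRNA")
    return MatchedSet("non_circ", members)


def matched_sample(
    pool: Sequence[Hashable],
    targets: Sequence[float],
    property_of: Callable[[Hashable], float],
    seed: int = 0,
    kind: str = "expression_adjusted",
    tolerance_fraction: float = 0.25,
) -> MatchedSet:
    """Draw, for each target value, the pool member nearest in the
    property, without replacement (ties broken by a seeded shuffle).

    The achieved mean is reported against the target mean; drift beyond
    ``tolerance_fraction`` of the target mean raises a warning rather
    than failing silently.
    """
    if len(pool) < len(targets):
        raise ValueError(
            f"pool ({len(pool)}) smaller than targets ({len(targets)}); "
            "consider sampling with replacement"
        )
    rng = np.random.default_rng(seed)
    pool = list(pool)
    order = rng.permutation(len(pool))  # seeded tie-break
    shuffled = [pool[i] for i in order]
    values = np.array([property_of(m) for m in shuffled], dtype=float)
    available = np.ones(len(shuffled), dtype=bool)
    members = []
    achieved = []
    for t in targets:
        idx_avail = np.nonzero(available)[0]
        diffs = np.abs(values[idx_avail] - t)
        pick = idx_avail[int(np.argmin(diffs))]
        available[pick] = False
        members.append(shuffled[pick])
        achieved.append(values[pick])
    t_mean = float(np.mean(targets)) if len(targets) else float("nan")
    a_mean = float(np.mean(achieved)) if achieved else float("nan")
    if (
        len(targets)
        and t_mean != 0
        and abs(a_mean - t_mean) > tolerance_fraction * abs(t_mean)
    ):
        warnings.warn(
            f"{kind}: achieved mean {a_mean:.4g} deviates from target "
            f"mean {t_mean:.4g} by more than {tolerance_fraction:.0%}"
        )
    return MatchedSet(kind, members, seed=seed, target_mean=t_mean,
                      achieved_mean=a_mean)


def largest_remainder_allocation(
    probs: Mapping[int, float], n: int
) -> dict[int, int]:
    """Allocate n counts to categories proportionally, distributing the
    remainder to the largest fractional parts (ties by category order)."""
    keys = sorted(probs)
    total = sum(probs[k] for k in keys)
    shares = {k: n * probs[k] / total for k in keys}
    counts = {k: int(np.floor(shares[k])) for k in keys}
    remainder = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(shares[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def position_adjusted_sample(
    pool_by_position: Mapping[int, Sequence[Hashable]],
    target_distribution: Mapping[int, float],
    n: int,
    seed: int = 0,
) -> MatchedSet:
    """Sample n features whose empirical ordinal-position distribution
    matches the target (largest-remainder count allocation per position,
    then seeded without-replacement sampling within each position)."""
    total = sum(target_distribution.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("target distribution must sum to 1")
    counts = largest_remainder_allocation(target_distribution, n)
    missing = [
        pos for pos, c in counts.items()
        if c > 0 and len(pool_by_position.get(pos, ())) < c
    ]
    if missing:
        raise ValueError(
            "pool lacks enough features at ordinal position(s) "
            + ", ".join(str(p) for p in missing)
        )
    rng = np.random.default_rng(seed)
    members = []
    for pos in sorted(counts):
        c = counts[pos]
        if c == 0:
            continue
        candidates = list(pool_by_position[pos])
        picked = rng.choice(len(candidates), size=c, replace=False)
        members.extend((pos, candidates[i]) for i in sorted(picked))
    return MatchedSet(
        "position_adjusted",
        members,
        seed=seed,
        notes={"allocation": counts},
    )
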