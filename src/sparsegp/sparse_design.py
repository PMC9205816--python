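"""Sparse-testing allocation of lines to selection environments.

Two schemes are implemented: *non-overlapping* (lines partitioned into one
unique calibration set per SE, sizes differing by at most one) and
*p% overlap* (a common subset phenotyped in every SE plus equal-size unique
sets).  The overlap count is the smallest ``x >= fraction * n`` for which
``n - x`` divides evenly over the environments, which reproduces the
published counts 28/58/88/112/142 for n=280 and k=6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "AllocationPlan",
    "overlap_count",
    "allocate_nonoverlap",
    "allocate_overlap",
    "replicate_plans",
    "mask_phenotypes",
]


@dataclass
class AllocationPlan:
    """Line -> tested-environments mapping for one randomization repeat."""

    repeat_index: int
    overlap_fraction: float
    tested: dict[str, frozenset[str]]
    overlap_set: frozenset[str]
    unique_sets: dict[str, frozenset[str]]
    seed: int
    env_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        uniq_union: set[str] = set()
        for env, s in self.unique_sets.items():
            if s & self.overlap_set:
                raise ValueError("overlap set intersects a unique set")
            if s & uniq_union:
                raise ValueError("unique sets are not pairwise disjoint")
            uniq_union |= s
        if uniq_union | self.overlap_set != set(self.tested):
            raise ValueError("unique sets plus overlap set must cover all lines")
        for line, envs in self.tested.items():
            if not envs:
                raise ValueError(f"line {line!r} is tested nowhere")

    @property
    def line_ids(self) -> list[str]:
        return list(self.tested)

    def calibration_set(self, env: str) -> set[str]:
        return {l for l, envs in self.tested.items() if env in envs}

    def prediction_set(self, env: str) -> set[str]:
        return {l for l, envs in self.tested.items() if env not in envs}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (line, env, int(env in envs), self.repeat_index)
            for line, envs in self.tested.items()
            for env in self.env_ids
        ]
        return pd.DataFrame(rows, columns=["line", "env", "tested_flag", "repeat_index"])


def overlap_count(n_lines: int, n_envs: int, fraction: float) -> int:
    """Number of lines phenotyped in *all* environments for a target
    overlap fraction: the smallest ``x >= fraction*n`` with ``(n - x)``
    divisible by ``n_envs`` (so the unique sets are exactly equal-sized)."""
    if n_envs < 2:
        raise ValueError("need at least 2 environments")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0:
        return 0
    x = int(np.ceil(fraction * n_lines - 1e-9))
    while (n_lines - x) % n_envs != 0:
        x += 1
    if x >= n_lines:
        raise ValueError("overlap would consume every line, leaving no prediction set")
    return x


def _family_major_order(
    rng: np.random.Generator, line_ids: list[str], families: dict[str, str]
) -> list[str]:
    """Lines grouped by family, family order and within-family order both
    randomized (the basis for family-stratified dealing)."""
    by_fam: dict[str, list[str]] = {}
    for l in line_ids:
        by_fam.setdefault(families.get(l, l), []).append(l)
    fams = list(by_fam)
    out: list[str] = []
    for fi in rng.permutation(len(fams)):
        members = by_fam[fams[fi]]
        out.extend(members[i] for i in rng.permutation(len(members)))
    return out


def _partition(
    rng: np.random.Generator, items: list[str], k: int,
    families: dict[str, str] | None = None,
) -> list[list[str]]:
    """Random partition into k groups with sizes differing by at most one;
    which groups get the larger size is itself randomized.  With a
    line -> family mapping, lines are dealt round-robin in family-major
    order, so members of a family of size <= k land in distinct groups."""
    if families is not None:
        order = _family_major_order(rng, items, families)
        start = int(rng.integers(k))
        groups: list[list[str]] = [[] for _ in range(k)]
        for j, l in enumerate(order):
            groups[(start + j) % k].append(l)
        return groups
    perm = [items[i] for i in rng.permutation(len(items))]
    base, extra = divmod(len(perm), k)
    sizes = np.full(k, base)
    sizes[rng.choice(k, size=extra, replace=False)] += 1
    out, pos = [], 0
    for s in sizes:
        out.append(perm[pos:pos + s])
        pos += s
    return out


def allocate_nonoverlap(
    line_ids, env_ids, seed: int, repeat_index: int = 0,
    families: dict[str, str] | None = None,
) -> AllocationPlan:
    """Partition lines into one unique calibration set per environment.

    Randomization is line-level simple random sampling; passing a
    line -> family mapping switches to family-stratified dealing.
    """
    line_ids, env_ids = list(line_ids), list(env_ids)
    if len(line_ids) < len(env_ids):
        raise ValueError("fewer lines than environments")
    rng = np.random.default_rng(seed)
    groups = _partition(rng, line_ids, len(env_ids), families)
    unique_sets = {env: frozenset(g) for env, g in zip(env_ids, groups)}
    tested = {l: frozenset({env}) for env, g in unique_sets.items() for l in g}
    return AllocationPlan(
        repeat_index, 0.0, tested, frozenset(), unique_sets, seed, env_ids
    )


def allocate_overlap(
    line_ids, env_ids, fraction: float, seed: int, repeat_index: int = 0,
    families: dict[str, str] | None = None,
) -> AllocationPlan:
    """Overlap scheme: ``overlap_count`` lines tested everywhere, the rest
    split into equal unique sets (exact division by construction)."""
    line_ids, env_ids = list(line_ids), list(env_ids)
    if fraction <= 0:
        raise ValueError("fraction must be positive; use allocate_nonoverlap for 0")
    x = overlap_count(len(line_ids), len(env_ids), fraction)
    rng = np.random.default_rng(seed)
    if families is not None:
        order = _family_major_order(rng, line_ids, families)
        # spread the everywhere-tested subset over families
        step = len(order) / x
        take = {order[int(i * step)] for i in range(x)}
        perm = sorted(take) + [l for l in order if l not in take]
    else:
        perm = [line_ids[i] for i in rng.permutation(len(line_ids))]
    overlap = frozenset(perm[:x])
    groups = _partition(rng, perm[x:], len(env_ids), families)
    unique_sets = {env: frozenset(g) for env, g in zip(env_ids, groups)}
    all_envs = frozenset(env_ids)
    tested = {l: all_envs for l in overlap}
    tested.update({l: frozenset({env}) for env, g in unique_sets.items() for l in g})
    return AllocationPlan(repeat_index, fraction, tested, overlap, unique_sets, seed, env_ids)


def replicate_plans(
    allocator: Callable[..., AllocationPlan], n_repeats: int = 30, base_seed: int = 0
) -> list[AllocationPlan]:
    """Repeat an allocation ``n_repeats`` times with derived seeds
    ``base_seed + i``; each plan carries its repeat index."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return [allocator(seed=base_seed + i, repeat_index=i) for i in range(n_repeats)]


def mask_phenotypes(
    pheno: pd.DataFrame, plan: AllocationPlan
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Split a plot table into the sparse-testing training table and the
    list of masked (line, environment) truth cells.

    A plot is retained iff its line is tested in its environment under the
    plan.  Lines absent from the plan (e.g. checks) are retained everywhere
    and never appear in ``truth_cells``.
    """
    missing = set(plan.tested) - set(pheno["line"])
    if missing:
        raise ValueError(f"plan lines absent from phenotypes: {sorted(missing)[:5]}")
    in_plan = pheno["line"].isin(plan.tested)
    tested_mask = np.array(
        [
            (not p) or (env in plan.tested[line])
            for p, line, env in zip(in_plan, pheno["line"], pheno["env"])
        ]
    )
    training = pheno[tested_mask].copy()
    envs = plan.env_ids or sorted(pheno["env"].unique())
    truth_cells = [
        (line, env)
        for line, tested_envs in plan.tested.items()
        for env in envs
        if env not in tested_envs
    ]
    return training, truth_cells
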