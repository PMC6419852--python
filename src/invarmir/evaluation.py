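"""Validation of predicted miRNA-mRNA interactions.

Predicted pairs are checked two ways: against transfection experiments
(a pair counts as supported when the target's |log2 fold-change| after
over-expressing the miRNA exceeds a threshold, 0.3 by default) and against
a database of experimentally confirmed interactions.  A random-draw null
experiment calibrates how many confirmations chance alone produces.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .baselines import InteractionRanking

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _norm(s: str) -> str:
    return str(s).strip().lower()


@dataclass(frozen=True)
class GroundTruthDB:
    """Set of experimentally confirmed (miRNA, mRNA) pairs.

    Identifier matching is case-insensitive; mapping namespaces between
    sources is the caller's responsibility.
    """

    pairs: frozenset[Pair]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Pair]) -> "GroundTruthDB":
        norm = frozenset((_norm(a), _norm(b)) for a, b in pairs)
        if any(not a or not b for a, b in norm):
            raise ValueError("empty identifier in ground-truth pair")
        return cls(pairs=norm)

    @classmethod
    def from_csv(cls, path) -> "GroundTruthDB":
        df = pd.read_csv(path)
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def to_csv(self, path) -> None:
        pd.DataFrame(sorted(self.pairs), columns=["miRNA", "mRNA"]).to_csv(path, index=False)

    def __contains__(self, pair: Pair) -> bool:
        return (_norm(pair[0]), _norm(pair[1])) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class TransfectionTable:
    """Map (miRNA, mRNA) -> log2 fold-change measured after transfecting
    the miRNA.  Values must be finite."""

    log2fc: dict[Pair, float]

    @classmethod
    def from_pairs(cls, items: Iterable[tuple[str, str, float]]) -> "TransfectionTable":
        table = {}
        for a, b, v in items:
            v = float(v)
            if not np.isfinite(v):
                raise ValueError(f"non-finite log2 fold-change for ({a}, {b})")
            table[(_norm(a), _norm(b))] = v
        return cls(log2fc=table)

    @classmethod
    def from_csv(cls, path) -> "TransfectionTable":
        df = pd.read_csv(path)
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]))

    def to_csv(self, path) -> None:
        rows = [(a, b, v) for (a, b), v in sorted(self.log2fc.items())]
        pd.DataFrame(rows, columns=["miRNA", "mRNA", "log2fc"]).to_csv(path, index=False)

    def get(self, pair: Pair) -> float | None:
        return self.log2fc.get((_norm(pair[0]), _norm(pair[1])))

    def __len__(self) -> int:
        return len(self.log2fc)


@dataclass
class ConfirmationResult:
    """Outcome of validating a list of predicted pairs."""

    confirmed: list[Pair]
    uncheckable: list[Pair] = field(default_factory=list)

    @property
    def confirmed_count(self) -> int:
        return len(self.confirmed)

    @property
    def uncheckable_count(self) -> int:
        return len(self.uncheckable)


def top_k_overall(ranking: InteractionRanking, k: int) -> list[Pair]:
    """First ``k`` pairs of the ranking (best ranks)."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range for ranking of length {len(ranking)}")
    return ranking.pairs[:k]


def top_k_per_regulator(ranking: InteractionRanking, k: int) -> dict[str, list[Pair]]:
    """For each regulator, its ``k`` best-ranked pairs (fewer, with a
    warning, when the regulator has fewer ranked pairs)."""
    if k < 1:
        raise ValueError("k must be positive")
    out: dict[str, list[Pair]] = defaultdict(list)
    for reg, tgt in ranking.pairs:
        if len(out[reg]) < k:
            out[reg].append((reg, tgt))
    short = [r for r, lst in out.items() if len(lst) < k]
    if short:
        logger.warning("%d regulator(s) have fewer than k=%d ranked pairs", len(short), k)
    return dict(out)


def confirm_by_transfection(
    pairs: Sequence[Pair],
    table: TransfectionTable,
    threshold: float = 0.3,
) -> ConfirmationResult:
    """A pair is confirmed when present in the transfection table with
    |log2FC| strictly greater than ``threshold``; pairs absent from the
    table are reported separately as uncheckable."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    confirmed, uncheckable = [], []
    for pair in pairs:
        fc = table.get(pair)
        if fc is None:
            uncheckable.append(pair)
        elif abs(fc) > threshold:
            confirmed.append(pair)
    return ConfirmationResult(confirmed=confirmed, uncheckable=uncheckable)


def confirm_by_database(pairs: Sequence[Pair], db: GroundTruthDB) -> ConfirmationResult:
    """Count queried pairs present in the confirmed-interaction database."""
    confirmed = [p for p in pairs if p in db]
    return ConfirmationResult(confirmed=confirmed)


def null_experiment(
    pair_universe: Sequence[Pair],
    k: int,
    validator: Callable[[list[Pair]], int],
    n_regulators: int = 30,
    reps: int = 100,
    seed: int = 0,
) -> float:
    """Random-draw baseline: per repetition draw ``n_regulators`` regulators
    uniformly without replacement and, for each, ``k`` of its targets
    uniformly without replacement; apply the validator and average the
    confirmed counts over ``reps`` repetitions.
    """
    by_reg: dict[str, list[str]] = defaultdict(list)
    for reg, tgt in pair_universe:
        by_reg[reg].append(tgt)
    regs = sorted(by_reg)
    if len(regs) < n_regulators:
        raise ValueError(
            f"universe has {len(regs)} regulators, fewer than {n_regulators}"
        )
    short = [r for r in regs if len(by_reg[r]) < k]
    if short:
        raise ValueError(
            f"{len(short)} regulator(s) have fewer than k={k} targets in the universe"
        )
    rng = np.random.default_rng(seed)
    counts = np.empty(reps)
    for rep in range(reps):
        chosen = rng.choice(len(regs), size=n_regulators, replace=False)
        draw: list[Pair] = []
        for ri in chosen:
            reg = regs[ri]
            tgts = by_reg[reg]
            take = rng.choice(len(tgts), size=k, replace=False)
            draw.extend((reg, tgts[ti]) for ti in take)
        counts[rep] = validator(draw)
    return float(counts.mean())


def method_overlap(confirmed_lists: dict[str, Sequence[Pair]]) -> pd.DataFrame:
    """UpSet-style overlap table of confirmed pairs across methods.

    One row per non-empty membership class: boolean column per method plus
    the count of pairs belonging to exactly that set of methods, and a
    summary row per method with its total.
    """
    if len(confirmed_lists) < 2:
        raise ValueError("need at least 2 methods to overlap")
    methods = list(confirmed_lists)
    sets = {m: {( _norm(a), _norm(b)) for a, b in confirmed_lists[m]} for m in methods}
    membership: dict[tuple[bool, ...], int] = defaultdict(int)
    for pair in set().union(*sets.values()):
        key = tuple(pair in sets[m] for m in methods)
        membership[key] += 1
    rows = []
    for key in sorted(membership, reverse=True):
        row = dict(zip(methods, key))
        row["count"] = membership[key]
        rows.append(row)
    df = pd.DataFrame(rows, columns=[*methods, "count"])
    totals = {m: len(sets[m]) for m in methods}
    df.attrs["totals"] = totals
    return df


__all__ = [
    "GroundTruthDB",
    "TransfectionTable",
    "ConfirmationResult",
    "top_k_overall",
    "top_k_per_regulator",
    "confirm_by_transfection",
    "confirm_by_database",
    "null_experiment",
    "method_overlap",
]
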