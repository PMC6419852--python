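"""miRNA-miRNA synergy: hypergeometric overlap of predicted target sets.

Two miRNAs are called synergistic when they share more predicted target
mRNAs than expected by chance.  For a universe of N mRNAs, miRNA_i with K
targets and miRNA_j with M targets sharing n, the p-value is the upper
hypergeometric tail P(X >= n) = 1 - sum_{x<n} C(K,x) C(N-K,M-x) / C(N,M).
All pairwise p-values are adjusted jointly by Benjamini-Hochberg and
called at an FDR cutoff (0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def hypergeom_pvalue(N: int, K: int, M: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= n).

    ``N``: universe size; ``K``, ``M``: the two target-set sizes; ``n``:
    shared targets.  Evaluated through the hypergeometric survival function
    (log-gamma based, numerically stable for large arguments).
    """
    for name, v in (("N", N), ("K", K), ("M", M), ("n", n)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, M, n = int(N), int(K), int(M), int(n)
    if K > N or M > N:
        raise ValueError(f"set sizes K={K}, M={M} cannot exceed universe N={N}")
    if not max(0, K + M - N) <= n <= min(K, M):
        raise ValueError(
            f"shared count n={n} outside feasible range "
            f"[{max(0, K + M - N)}, {min(K, M)}] for N={N}, K={K}, M={M}"
        )
    if n == 0:
        return 1.0
    return float(stats.hypergeom.sf(n - 1, N, K, M))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, each p_(i) is scaled by m/i, monotonicity is enforced
    from the largest down, and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass
class SynergyResult:
    """All-pairs synergy test output.

    Matrices are symmetric with NaN diagonals (a miRNA is never tested
    against itself); ``synergistic`` is True where the BH-adjusted p-value
    falls below the cutoff.
    """

    regulator_ids: list[str]
    raw_p: np.ndarray
    adj_p: np.ndarray
    synergistic: np.ndarray
    shared: np.ndarray          # pairwise shared-target counts n
    set_sizes: np.ndarray       # per-regulator K (= M by symmetry)
    universe_size: int
    cutoff: float

    def to_long(self) -> pd.DataFrame:
        rows = []
        r = len(self.regulator_ids)
        for i in range(r):
            for j in range(i + 1, r):
                rows.append({
                    "miRNA_i": self.regulator_ids[i],
                    "miRNA_j": self.regulator_ids[j],
                    "shared": int(self.shared[i, j]),
                    "raw_p": self.raw_p[i, j],
                    "adj_p": self.adj_p[i, j],
                    "synergistic": bool(self.synergistic[i, j]),
                })
        return pd.DataFrame(rows)


def synergy_matrix(
    target_sets: dict[str, set[str]],
    universe_size: int,
    cutoff: float = 0.05,
) -> SynergyResult:
    """Test every unordered miRNA pair for significant target-set overlap.

    ``target_sets`` maps each regulator to its predicted target set (all
    subsets of a universe of ``universe_size`` mRNAs).  Raw p-values come
    from :func:`hypergeom_pvalue`; BH adjustment pools all C(r, 2) pairs as
    one family.
    """
    regs = list(target_sets)
    if len(regs) < 2:
        raise ValueError("need at least 2 regulators")
    sizes = np.array([len(target_sets[r]) for r in regs])
    if sizes.max(initial=0) > universe_size:
        raise ValueError("a target set is larger than the universe")
    r = len(regs)
    raw = np.full((r, r), np.nan)
    shared = np.zeros((r, r), dtype=int)
    flat, idx = [], []
    for i in range(r):
        for j in range(i + 1, r):
            n = len(target_sets[regs[i]] & target_sets[regs[j]])
            shared[i, j] = shared[j, i] = n
            p = hypergeom_pvalue(universe_size, int(sizes[i]), int(sizes[j]), n)
            raw[i, j] = raw[j, i] = p
            flat.append(p)
            idx.append((i, j))
    adj_flat = bh_adjust(np.array(flat))
    adj = np.full((r, r), np.nan)
    syn = np.zeros((r, r), dtype=bool)
    for (i, j), a in zip(idx, adj_flat):
        adj[i, j] = adj[j, i] = a
        syn[i, j] = syn[j, i] = a < cutoff
    return SynergyResult(
        regulator_ids=regs,
        raw_p=raw,
        adj_p=adj,
        synergistic=syn,
        shared=shared,
        set_sizes=sizes,
        universe_size=universe_size,
        cutoff=cutoff,
    )


def min_synergy_partners(result: SynergyResult) -> int:
    """Minimum over miRNAs of the number of synergistic partners (how many
    other miRNAs each one significantly shares targets with)."""
    if len(result.regulator_ids) < 2:
        raise ValueError("need at least 2 regulators")
    return int(result.synergistic.sum(axis=1).min())


__all__ = [
    "hypergeom_pvalue",
    "bh_adjust",
    "SynergyResult",
    "synergy_matrix",
    "min_synergy_partners",
]
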