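"""Pattern-heterogeneity search over partitions of the strata.

A partition divides the G strata into disjoint blocks; each block is
fitted under its best proportionality model (singletons get the
unconstrained single-stratum model), and the partition is scored by a
partition-level AICc assembled from the summed block log-likelihoods and
parameter counts. The number of partitions is the Bell number B(G), so an
exhaustive search is practical for roughly 2 <= G <= 8 and capped at
G = 12 (B(12) = 4,213,597).

Subset fits are computed once and cached; partition scores are assembled
from the cache, so results are identical regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .apc import fit_apc
from .errors import CapcaError, LexisValidationError
from .lexis import StratifiedLexis
from .stratified import PH_SPECS, aicc, fit_constrained

G_CAP = 12

_MODEL_LETTER = {"PH-L": "L", "PH-T": "T", "PH-X": "X", "PH-A": "A", "N-PH": "N"}


def bell_number(G: int) -> int:
    """Number of set partitions of G elements (exact integer arithmetic).

    Uses the Bell-triangle recurrence; B(0) = 1 by the empty-set
    convention.
    """
    if G < 0:
        raise ValueError(f"G must be non-negative, got {G}")
    row = [1]
    for _ in range(G):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]


def enumerate_subsets(G: int) -> list[tuple[int, ...]]:
    """All 2^G - 1 non-empty subsets of {1..G}, by size then lexicographic."""
    if G < 1:
        raise ValueError(f"G must be >= 1, got {G}")
    out: list[tuple[int, ...]] = []
    for size in range(1, G + 1):
        out.extend(combinations(range(1, G + 1), size))
    return out


def _rgs_iter(G: int) -> Iterator[tuple[int, ...]]:
    """Restricted-growth strings of length G in lexicographic order."""
    code = [0] * G

    def rec(i: int, max_used: int):
        if i == G:
            yield tuple(code)
            return
        for v in range(max_used + 2):
            code[i] = v
            yield from rec(i + 1, max(max_used, v))

    yield from rec(1, 0) if G > 0 else iter(())


def enumerate_partitions(G: int) -> list[tuple[tuple[int, ...], ...]]:
    """All B(G) partitions of {1..G} in canonical deterministic order.

    Each partition is a tuple of disjoint blocks covering {1..G}; blocks
    are ordered by their smallest member (the natural order of
    restricted-growth-string codes). Capped at G = 12; beyond that one
    must restrict the strata or the evaluated partitions.
    """
    if G < 1:
        raise ValueError(f"G must be >= 1, got {G}")
    if G > G_CAP:
        raise CapcaError(
            f"G = {G} exceeds the partition-enumeration cap {G_CAP} "
            f"(B({G_CAP}) = {bell_number(G_CAP):,}); restrict the strata or "
            "evaluated partitions"
        )
    partitions = []
    for code in _rgs_iter(G):
        nblocks = max(code) + 1
        blocks: list[list[int]] = [[] for _ in range(nblocks)]
        for i, v in enumerate(code):
            blocks[v].append(i + 1)
        partitions.append(tuple(tuple(b) for b in blocks))
    return partitions


def correspondence_matrix(
    partitions: Sequence[tuple[tuple[int, ...], ...]],
    subsets: Sequence[tuple[int, ...]],
) -> np.ndarray:
    """B x N matrix: entry (b, s) = order of subset s within partition b.

    Zero means the subset does not occur in that partition. Each row's
    nonzero entries index disjoint subsets covering {1..G} in block order
    1..(number of blocks).
    """
    index = {s: i for i, s in enumerate(subsets)}
    T = np.zeros((len(partitions), len(subsets)), dtype=int)
    for b, part in enumerate(partitions):
        for order, block in enumerate(part, start=1):
            if block not in index:
                raise LexisValidationError(
                    f"partition block {block} missing from subset catalog"
                )
            T[b, index[block]] = order
    return T


@dataclass(frozen=True)
class SubsetFit:
    """Cached best fit for one subset of strata."""

    subset: tuple[int, ...]
    model: str  # spec name, or "U" for the unconstrained singleton fit
    loglik: float
    k: int
    error: str = ""

    @property
    def letter(self) -> str:
        return _MODEL_LETTER.get(self.model, "U")


@dataclass(frozen=True)
class MultiplexReport:
    """Ranked partition table from a multiplex analysis.

    ``table`` rows are in canonical partition order with the
    partition-level AICc and its differential Delta vs the optimum;
    ``optimal_partition`` is the argmin (ties broken by the lowest
    canonical partition index; ties, if any, are flagged in the table).
    """

    labels: tuple[str, ...]
    table: pd.DataFrame
    subset_fits: dict[tuple[int, ...], SubsetFit]
    optimal_index: int

    @property
    def optimal_partition(self) -> tuple[tuple[int, ...], ...]:
        return self.table.loc[self.optimal_index, "partition"]

    @property
    def optimal_blocks(self) -> str:
        return self.table.loc[self.optimal_index, "blocks"]

    @property
    def optimal_models(self) -> str:
        return self.table.loc[self.optimal_index, "block_models"]

    def to_csv(self, path) -> None:
        cols = ["partition_id", "blocks", "block_models", "loglik", "k",
                "aicc", "delta_aicc", "selected", "tie", "error"]
        self.table[cols].to_csv(path, index=False)


def _fit_subset(
    data: StratifiedLexis, subset: tuple[int, ...], specs: Sequence[str]
) -> SubsetFit:
    labels = [data.labels[i - 1] for i in subset]
    sub = data.subset(labels)
    n_sub = len(subset) * data.grid.A * data.grid.P
    if len(subset) == 1:
        fit = fit_apc(sub.strata[0], sub.grid)
        return SubsetFit(subset, "U", fit.loglik, fit.k)
    best: SubsetFit | None = None
    errs = []
    for name in specs:
        try:
            f = fit_constrained(sub, name)
        except CapcaError as exc:
            errs.append(f"{name}: {exc}")
            continue
        score = aicc(f.loglik, f.k, n_sub)
        if best is None or score < best_score:
            best, best_score = SubsetFit(subset, name, f.loglik, f.k), score
    if best is None:
        return SubsetFit(subset, "", np.nan, 0, error="; ".join(errs))
    return best


def multiplex_analysis(
    data: StratifiedLexis,
    specs: Sequence[str] = PH_SPECS,
) -> MultiplexReport:
    """Exhaustive partition search ranked by partition-level AICc.

    For each non-singleton subset the best of ``specs`` by subset-level
    AICc is cached; singleton subsets get the unconstrained single-stratum
    model. Partition scores are AICc(sum loglik, sum k, n = G*A*P): the
    small-sample correction is non-additive, so it is recomputed at the
    partition level rather than summed across blocks.
    """
    G = data.G
    if G < 2:
        raise LexisValidationError("multiplex analysis requires at least two strata")
    if G > G_CAP:
        raise CapcaError(f"G = {G} exceeds the cap {G_CAP}")
    subsets = enumerate_subsets(G)
    partitions = enumerate_partitions(G)
    n_total = G * data.grid.A * data.grid.P

    cache = {s: _fit_subset(data, s, specs) for s in subsets}

    rows = []
    for b, part in enumerate(partitions):
        fits = [cache[block] for block in part]
        failed = [f for f in fits if f.error]
        if failed:
            rows.append(
                {"partition_id": b + 1, "partition": part,
                 "blocks": _render_blocks(part),
                 "block_models": "".join("{?}" for _ in part),
                 "loglik": np.nan, "k": np.nan, "aicc": np.nan,
                 "error": failed[0].error}
            )
            continue
        ll = sum(f.loglik for f in fits)
        k = sum(f.k for f in fits)
        try:
            score = aicc(ll, k, n_total)
        except CapcaError as exc:
            rows.append(
                {"partition_id": b + 1, "partition": part,
                 "blocks": _render_blocks(part),
                 "block_models": "".join("{%s}" % f.letter for f in fits),
                 "loglik": ll, "k": k, "aicc": np.nan, "error": str(exc)}
            )
            continue
        rows.append(
            {"partition_id": b + 1, "partition": part,
             "blocks": _render_blocks(part),
             "block_models": "".join("{%s}" % f.letter for f in fits),
             "loglik": ll, "k": k, "aicc": score, "error": ""}
        )
    table = pd.DataFrame(rows)
    scores = table["aicc"].to_numpy(float)
    if np.all(np.isnan(scores)):
        raise CapcaError("every partition failed to fit")
    best = int(np.nanargmin(scores))
    table["delta_aicc"] = table["aicc"] - table.loc[best, "aicc"]
    table["selected"] = [i == best for i in range(len(table))]
    table["tie"] = np.isclose(table["aicc"], table.loc[best, "aicc"], rtol=0, atol=1e-9) & ~table["selected"]
    return MultiplexReport(
        labels=tuple(data.labels),
        table=table,
        subset_fits=cache,
        optimal_index=best,
    )


def _render_blocks(part: tuple[tuple[int, ...], ...]) -> str:
    return "|".join("{" + ",".join(str(i) for i in block) + "}" for block in part)
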