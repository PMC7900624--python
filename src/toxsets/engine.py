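"""AFC/AAFC activation scores with resampled background nulls.

Two set-level statistics over log fold changes:

* **AFC** (aggregated fold change): the sum of the log FC values of the
  set's genes. Its sign is the direction of regulation (positive = net
  up-regulation).
* **AAFC** (aggregated absolute fold change): the sum of |log FC|,
  measuring disruption regardless of direction.

Significance is assessed against a resampled null: each of ``n_draws``
iterations (default 10,000) picks ``n_matched`` fold-change values
uniformly *without replacement* from the full background table and
applies the same statistic — i.e. the null is "a random gene set of the
same size from this experiment". The z-score is the number of null
standard deviations between the observed score and the null mean; the
empirical p-value is the add-one upper-tail fraction
``(#draws >= observed + 1) / (n_draws + 1)``, the probability that a
random set scores at least as high as the observed one. For AFC a
strongly down-regulated set therefore has p near 1 by construction;
its negative z-score carries the direction. For AAFC only positive
z-scores indicate activation, so ``aafc_significant`` is false at
z <= 0.

Gene-level p-values, when supplied, are combined per set with Fisher's
method: X = -2 sum(ln p_i) referred to a chi-square distribution with
2k degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from toxsets.errors import (
    CombinatorialLimitError,
    DegenerateNullError,
    DomainError,
)
from toxsets.expression_io import ExpressionTable, background_values
from toxsets.geneset_io import GeneSet, GeneSetCollection

Method = Literal["afc", "aafc"]
Tail = Literal["upper", "lower"]

#: Floor applied to gene-level p-values before taking logs.
P_FLOOR = 1e-300

#: Refuse exhaustive enumeration beyond this many subsets.
EXHAUSTIVE_LIMIT = 10**6


@dataclass(frozen=True)
class NullConfig:
    """Resampling-null settings.

    ``n_draws`` random same-size sets per null (default 10,000); ``seed``
    feeds a single NumPy generator per run so results are reproducible.
    Draws are always without replacement within an iteration.
    """

    n_draws: int = 10_000
    seed: int = 17
    #: fixed: each draw samples without replacement (a random same-size
    #: gene set); with-replacement nulls are not offered.
    replacement: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise DomainError("n_draws must be >= 1")
        if self.replacement:
            raise DomainError("sampling is always without replacement")


@dataclass(frozen=True)
class NullDistribution:
    """Resampled score values for one (method, sample size) pair."""

    method: Method
    sample_size: int
    draws: np.ndarray
    mean: float
    sd: float

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


@dataclass
class ActivationResult:
    """Scores, z, p, direction and Fisher's combined p for one gene set.

    Unscored sets (fewer than ``min_matched`` genes found in the table)
    carry ``None`` in the numeric fields and the ``"unscored"`` flag; a
    degenerate null (zero spread) yields z = 0, p = 1 and the
    ``"degenerate"`` flag.
    """

    set_name: str
    n_set: int
    n_matched: int
    afc_score: float | None = None
    afc_z: float | None = None
    afc_p: float | None = None
    direction: str | None = None
    aafc_score: float | None = None
    aafc_z: float | None = None
    aafc_p: float | None = None
    aafc_significant: bool | None = None
    fisher_p: float | None = None
    fisher_k: int | None = None
    flags: tuple[str, ...] = ()
    # Benjamini-Hochberg adjusted p-values, filled by report.rank_results
    # when adjustment is requested.
    afc_p_adj: float | None = None
    aafc_p_adj: float | None = None
    fisher_p_adj: float | None = None

    @property
    def unscored(self) -> bool:
        return "unscored" in self.flags

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def afc_score(values: Sequence[float]) -> float:
    """Aggregated fold change: the plain sum of log FC values."""
    if len(values) == 0:
        raise DomainError("afc_score of an empty value list")
    return float(np.sum(np.asarray(values, dtype=float)))


def aafc_score(values: Sequence[float]) -> float:
    """Aggregated absolute fold change: the sum of |log FC|."""
    if len(values) == 0:
        raise DomainError("aafc_score of an empty value list")
    return float(np.sum(np.abs(np.asarray(values, dtype=float))))


def _draw_index_matrix(
    rng: np.random.Generator, n_pop: int, k: int, n_draws: int
) -> np.ndarray:
    """(n_draws, k) indices, each row a uniform k-subset of range(n_pop).

    Small k relative to the population: rejection sampling (draw with
    replacement, redraw rows containing a repeat) — exact, because
    conditioning an iid uniform tuple on distinctness gives the uniform
    distribution over ordered k-subsets. Larger k: take the k smallest of
    n_pop iid uniforms per row, chunked to bound memory.
    """
    if k * (k - 1) <= n_pop:
        idx = rng.integers(0, n_pop, size=(n_draws, k))
        if k > 1:
            while True:
                srt = np.sort(idx, axis=1)
                bad = (np.diff(srt, axis=1) == 0).any(axis=1)
                n_bad = int(bad.sum())
                if n_bad == 0:
                    break
                idx[bad] = rng.integers(0, n_pop, size=(n_bad, k))
        return idx
    chunk = max(1, int(2e6) // n_pop)
    out = np.empty((n_draws, k), dtype=np.intp)
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        u = rng.random((stop - start, n_pop))
        out[start:stop] = np.argpartition(u, k - 1, axis=1)[:, :k]
    return out


def sample_null(
    background: Sequence[float],
    sample_size: int,
    method: Method,
    config: NullConfig | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Resample the null score distribution for one set size.

    Each draw selects ``sample_size`` values uniformly without replacement
    from ``background`` and applies the method's score. Pass ``rng`` to
    consume an existing generator (one shared stream per run); otherwise a
    fresh generator is seeded from ``config.seed``, making standalone
    calls bit-reproducible.

    Raises
    ------
    DegenerateNullError
        If ``sample_size >= len(background)`` (no variation possible).
    DomainError
        If ``sample_size < 1`` or the background has fewer than 2 values.
    """
    config = config or NullConfig()
    bg = np.asarray(background, dtype=float)
    if bg.size < 2:
        raise DomainError("background needs at least 2 values")
    if sample_size < 1:
        raise DomainError("sample_size must be >= 1")
    if sample_size >= bg.size:
        raise DegenerateNullError(
            f"sample size {sample_size} >= background size {bg.size}: "
            "the resampled null has no variation"
        )
    if method not in ("afc", "aafc"):
        raise DomainError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = _draw_index_matrix(rng, bg.size, sample_size, config.n_draws)
    pool = np.abs(bg) if method == "aafc" else bg
    draws = pool[idx].sum(axis=1)
    return NullDistribution(
        method=method,
        sample_size=sample_size,
        draws=draws,
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=0)),
    )


def z_score(actual: float, null: NullDistribution) -> float:
    """Standardized distance of the observed score from the null mean.

    A degenerate null (sd = 0) yields 0.0; callers flag that case rather
    than raising, so one constant-background set cannot abort a batch.
    """
    if null.sd == 0.0:
        return 0.0
    return (actual - null.mean) / null.sd


def empirical_p(actual: float, null: NullDistribution, tail: Tail = "upper") -> float:
    """Add-one empirical tail probability of the observed score.

    Upper tail: ``(#draws >= actual + 1) / (n_draws + 1)``; lower tail
    symmetric. The add-one correction keeps the result in (0, 1] —
    finite resampling can never certify p = 0.
    """
    draws = null.draws
    if tail == "upper":
        r = int(np.count_nonzero(draws >= actual))
    elif tail == "lower":
        r = int(np.count_nonzero(draws <= actual))
    else:
        raise DomainError(f"unknown tail {tail!r}")
    return (r + 1) / (len(draws) + 1)


def exhaustive_null(
    background: Sequence[float], sample_size: int, method: Method
) -> np.ndarray:
    """Exact null: the score of every size-``sample_size`` subset.

    Enumeration oracle for the resampled null — exact tail probabilities
    and moments follow directly. Refuses instances with more than
    ``EXHAUSTIVE_LIMIT`` subsets.
    """
    bg = np.asarray(background, dtype=float)
    if not 1 <= sample_size <= bg.size:
        raise DomainError("sample_size out of range for exhaustive null")
    n_subsets = math.comb(bg.size, sample_size)
    if n_subsets > EXHAUSTIVE_LIMIT:
        raise CombinatorialLimitError(
            f"C({bg.size}, {sample_size}) = {n_subsets} exceeds "
            f"{EXHAUSTIVE_LIMIT} subsets"
        )
    pool = np.abs(bg) if method == "aafc" else bg
    return np.fromiter(
        (pool[list(c)].sum() for c in combinations(range(bg.size), sample_size)),
        dtype=float,
        count=n_subsets,
    )


def fisher_combined(
    p_values: Sequence[float | None],
) -> tuple[float | None, int]:
    """Fisher's combined probability over the available gene p-values.

    Absent values are dropped; the rest are floored at 1e-300 before the
    log. Returns ``(combined_p, k)`` where X = -2 sum(ln p_i) is referred
    to chi-square with 2k degrees of freedom; ``(None, 0)`` when no
    p-values are available (not an error — the column is optional).
    """
    ps = [p for p in p_values if p is not None]
    if not ps:
        return None, 0
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise DomainError(f"p-value {p} outside (0, 1]")
    k = len(ps)
    x = -2.0 * sum(math.log(max(p, P_FLOOR)) for p in ps)
    # the survival function underflows for extreme X; keep the result in (0, 1]
    return max(float(stats.chi2.sf(x, df=2 * k)), P_FLOOR), k


def score_gene_set(
    table: ExpressionTable,
    gene_set: GeneSet,
    config: NullConfig | None = None,
    min_matched: int = 3,
    rng: np.random.Generator | None = None,
    _background: np.ndarray | None = None,
) -> ActivationResult:
    """Score one gene set against the table's background.

    Set members are intersected with the table; with fewer than
    ``min_matched`` genes found the set is returned unscored (flagged,
    never dropped, never an exception). Otherwise AFC and AAFC scores are
    computed on the matched log FC values, one null per method is
    resampled at sample size ``n_matched``, and both p-values are the
    upper-tail probability that a random same-size set scores at least
    as high. Fisher's combined p uses the matched genes that carry
    gene-level p-values.
    """
    config = config or NullConfig()
    matched = sorted(g for g in gene_set.members if g in table.records)
    result = ActivationResult(
        set_name=gene_set.name,
        n_set=len(gene_set.members),
        n_matched=len(matched),
    )
    if len(matched) < max(min_matched, 1):
        result.flags = ("unscored",)
        return result

    values = np.array([table.records[g].log_fc for g in matched])
    result.afc_score = float(values.sum())
    result.aafc_score = float(np.abs(values).sum())
    result.direction = "up" if result.afc_score >= 0 else "down"
    result.fisher_p, result.fisher_k = fisher_combined(
        [table.records[g].gene_p for g in matched]
    )

    bg = (
        _background
        if _background is not None
        else np.asarray(background_values(table))
    )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    try:
        null_afc = sample_null(bg, len(matched), "afc", config, rng)
        null_aafc = sample_null(bg, len(matched), "aafc", config, rng)
    except DegenerateNullError:
        null_afc = null_aafc = None
    if null_afc is None or null_afc.degenerate or null_aafc.degenerate:
        result.afc_z = result.aafc_z = 0.0
        result.afc_p = result.aafc_p = 1.0
        result.aafc_significant = False
        result.flags = ("degenerate",)
        return result

    result.afc_z = z_score(result.afc_score, null_afc)
    result.afc_p = empirical_p(result.afc_score, null_afc, "upper")
    result.aafc_z = z_score(result.aafc_score, null_aafc)
    result.aafc_p = empirical_p(result.aafc_score, null_aafc, "upper")
    result.aafc_significant = result.aafc_z > 0
    return result


def score_collection(
    table: ExpressionTable,
    collection: GeneSetCollection,
    config: NullConfig | None = None,
    min_matched: int = 3,
) -> list[ActivationResult]:
    """Score every set in a collection with one shared seeded stream.

    Sets are scored in sorted set-name order so the random stream each
    set consumes — and hence every number produced — is independent of
    the order of lines in the GMT file.
    """
    config = config or NullConfig()
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(background_values(table))
    return [
        score_gene_set(
            table,
            gene_set,
            config=config,
            min_matched=min_matched,
            rng=rng,
            _background=bg,
        )
        for gene_set in sorted(collection.sets, key=lambda s: s.name)
    ]
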