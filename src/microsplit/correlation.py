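"""Pairwise Spearman co-occurrence networks with Benjamini-Hochberg FDR.

Within one sample group, every unordered feature pair receives a Spearman
rank correlation (average ranks on ties), a two-sided p-value from the
t-distribution approximation, and a BH-adjusted q-value over all pairs
tested in the same call (the FDR family is one group x rank analysis).
Edges are then thresholded at ``|rho| > rho_min`` and ``q < q_max`` — the
absolute value is used with the sign retained, so strong negative
co-exclusions survive alongside positive co-occurrences.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from microsplit.errors import ValidationError
from microsplit.io_model import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrEdge:
    """One pairwise association; endpoints are in canonical (sorted) order."""

    feature_a: str
    feature_b: str
    rho: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.feature_a >= self.feature_b:
            raise ValidationError(
                f"edge endpoints must be canonically ordered: "
                f"{self.feature_a!r} >= {self.feature_b!r}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.feature_a, self.feature_b)


@dataclass
class CorrNetwork:
    """Edges surviving the (rho_min, q_max) thresholds for one group."""

    group_label: str
    rank: Optional[str]
    edges: list[CorrEdge]
    thresholds: tuple[float, float]

    @property
    def features(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.feature_a)
            out.add(e.feature_b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Column-wise average ranks (standard Spearman tie handling)."""
    return np.apply_along_axis(stats.rankdata, 0, x)


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # |rho| == 1 gives t = inf -> p = 0
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return p


def _exact_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p-value for Spearman rho (tiny n only)."""
    n = len(a)
    if n > 8:
        raise ValueError("exact permutation p-value supported for n <= 8 only")
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    obs = abs(_pearson(ra, rb))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(_pearson(ra, rb[list(perm)]))
        if r >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else math.nan


def spearman_all_pairs(
    m: AbundanceMatrix,
    samples: Optional[Iterable[str]] = None,
    *,
    pvalue_method: str = "t",
) -> list[CorrEdge]:
    """Spearman correlation for every unordered feature pair of ``m``.

    Returns one :class:`CorrEdge` per pair in canonical order.  A feature
    constant across the chosen samples has undefined rank correlation: its
    pairs are emitted with ``rho = NaN`` and excluded from the BH family
    (the count is logged).  ``pvalue_method`` is ``"t"`` (default) or
    ``"exact"`` (full permutation null, n <= 8).
    """
    if pvalue_method not in ("t", "exact"):
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    sub = m.subset_samples(samples) if samples is not None else m
    n, p = sub.n_samples, sub.n_features
    if n < 4:
        raise ValidationError(f"need >= 4 samples for correlation, got {n}")
    if p < 2:
        raise ValidationError(f"need >= 2 features, got {p}")

    x = sub.values
    ranks = _rank_columns(x)
    constant = ranks.std(axis=0) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_mat = np.corrcoef(ranks, rowvar=False)
    # order features canonically so edge endpoints sort
    order = np.argsort(np.asarray(sub.feature_ids, dtype=object))
    feats = [sub.feature_ids[i] for i in order]

    pairs: list[tuple[int, int]] = []
    rhos: list[float] = []
    for ia, ib in itertools.combinations(range(p), 2):
        i, j = order[ia], order[ib]
        if constant[i] or constant[j]:
            rhos.append(math.nan)
        else:
            rhos.append(float(rho_mat[i, j]))
        pairs.append((ia, ib))

    rho_arr = np.asarray(rhos)
    valid = ~np.isnan(rho_arr)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info(
            "%d of %d feature pairs involve a constant feature; "
            "excluded from FDR adjustment",
            n_dropped,
            len(pairs),
        )

    pvals = np.full(len(pairs), math.nan)
    if pvalue_method == "t":
        pvals[valid] = _t_pvalue(rho_arr[valid], n)
    else:
        xs = sub.values[:, order]
        for k, (ia, ib) in enumerate(pairs):
            if valid[k]:
                pvals[k] = _exact_pvalue(xs[:, ia], xs[:, ib])

    qvals = np.full(len(pairs), math.nan)
    if valid.any():
        qvals[valid] = multipletests(pvals[valid], method="fdr_bh")[1]

    return [
        CorrEdge(feats[ia], feats[ib], float(rho_arr[k]), float(pvals[k]),
                 float(qvals[k]))
        for k, (ia, ib) in enumerate(pairs)
    ]


def threshold_network(
    edges: Sequence[CorrEdge],
    rho_min: float = 0.6,
    q_max: float = 0.05,
    *,
    keep_negative: bool = True,
    group_label: str = "",
    rank: Optional[str] = None,
) -> CorrNetwork:
    """Retain edges with ``|rho| > rho_min`` and ``q < q_max`` (strict).

    The comparison uses the absolute correlation with the sign kept on the
    retained edge; ``keep_negative=False`` additionally requires rho > 0.
    Pairs with undefined (NaN) correlation never pass.
    """
    if not (0.0 <= rho_min < 1.0):
        raise ValueError(f"rho_min must be in [0, 1), got {rho_min}")
    if not (0.0 < q_max <= 1.0):
        raise ValueError(f"q_max must be in (0, 1], got {q_max}")
    kept = [
        e
        for e in edges
        if not math.isnan(e.rho)
        and abs(e.rho) > rho_min
        and e.q < q_max
        and (keep_negative or e.rho > 0)
    ]
    return CorrNetwork(group_label, rank, kept, (rho_min, q_max))


def write_network_tsv(net: CorrNetwork, path: str | Path) -> None:
    """Serialize as TSV: feature_a, feature_b, rho, p, q."""
    df = pd.DataFrame(
        [(e.feature_a, e.feature_b, e.rho, e.p, e.q) for e in net.edges],
        columns=["feature_a", "feature_b", "rho", "p", "q"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_network_tsv(
    path: str | Path,
    *,
    group_label: str = "",
    rank: Optional[str] = None,
    thresholds: tuple[float, float] = (0.0, 1.0),
) -> CorrNetwork:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    edges = [
        CorrEdge(str(r.feature_a), str(r.feature_b), float(r.rho), float(r.p), float(r.q))
        for r in df.itertuples(index=False)
    ]
    return CorrNetwork(group_label, rank, edges, thresholds)
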