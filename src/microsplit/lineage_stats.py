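"""Two-proportion z-test on shared-ancestor edges between group networks.

For a co-occurrence network and a taxonomic rank, an edge "shares an
ancestor" when both endpoints carry the same taxon name at that rank.  Two
groups' networks are compared by the pooled two-proportion z statistic

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)),    p = (x1 + x2)/(n1 + n2)

with a two-sided normal p-value and no continuity correction.  Edges with an
endpoint lacking the rank (or mapped to the unassigned sentinel) are excluded
from both numerator and denominator: an unconfirmed lineage cannot witness a
common ancestor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from scipy import stats

from microsplit.correlation import CorrNetwork
from microsplit.errors import ValidationError
from microsplit.io_model import RANKS, Lineage

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p_value: float) -> str:
    for cutoff, stars in _STAR_LEVELS:
        if p_value < cutoff:
            return stars
    return "ns"


@dataclass(frozen=True)
class PropTestResult:
    """Result of the pooled two-proportion z-test at one ancestor rank."""

    rank: str
    x1: int
    n1: int
    x2: int
    n2: int
    p1_hat: float
    p2_hat: float
    p_pooled: float
    z: float
    p_value: float
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def shared_ancestor_count(
    net: CorrNetwork,
    lineages: Mapping[str, Lineage],
    rank: str,
) -> tuple[int, int]:
    """(x, n): same-ancestor edges and rank-informative edges of the network.

    n counts edges whose both endpoints have the rank assigned; x counts
    those whose rank values agree.  Endpoints missing from ``lineages``
    count as having no assignment at any rank.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomic rank {rank!r}")
    x = n = 0
    for e in net.edges:
        la = lineages.get(e.feature_a)
        lb = lineages.get(e.feature_b)
        va = la.get(rank) if la is not None else None
        vb = lb.get(rank) if lb is not None else None
        if va is None or vb is None:
            continue
        n += 1
        if va == vb:
            x += 1
    return x, n


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> PropTestResult:
    """Pooled-variance two-proportion z-test, two-sided, no continuity correction.

    Degenerate pools (x1 + x2 equal to 0 or to n1 + n2, so the pooled
    variance vanishes) report z = 0, p = 1 with the ``degenerate`` flag set.
    Swapping the groups negates z and preserves the p-value.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("two_proportion_z undefined for empty groups")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("counts must satisfy 0 <= x_i <= n_i")
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    degenerate = (x1 + x2) in (0, n1 + n2)
    if degenerate or p1 == p2:
        z = 0.0
        p_value = 1.0
    else:
        se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        z = (p1 - p2) / se
        p_value = 2.0 * stats.norm.sf(abs(z))
    return PropTestResult(
        rank="",
        x1=x1, n1=n1, x2=x2, n2=n2,
        p1_hat=p1, p2_hat=p2, p_pooled=pooled,
        z=z, p_value=p_value, degenerate=degenerate,
    )


def compare_groups(
    net1: CorrNetwork,
    net2: CorrNetwork,
    lineages: Mapping[str, Lineage],
    ranks: Sequence[str] = ("family", "order", "class", "phylum"),
) -> list[PropTestResult]:
    """Shared-ancestor proportion test between two group networks per rank.

    The two networks must come from distinct groups and the same taxonomic
    analysis rank; one result row is returned per requested ancestor rank.
    """
    if net1.group_label and net1.group_label == net2.group_label:
        raise ValidationError(
            f"networks must come from distinct groups, both are {net1.group_label!r}"
        )
    if net1.rank != net2.rank:
        raise ValidationError(
            f"networks analyzed at different ranks: {net1.rank!r} vs {net2.rank!r}"
        )
    out = []
    for rank in ranks:
        x1, n1 = shared_ancestor_count(net1, lineages, rank)
        x2, n2 = shared_ancestor_count(net2, lineages, rank)
        if n1 == 0 or n2 == 0:
            raise ValidationError(
                f"no rank-informative edges at {rank!r} "
                f"(n1={n1}, n2={n2}); cannot test"
            )
        r = two_proportion_z(x1, n1, x2, n2)
        out.append(
            PropTestResult(
                rank=rank,
                x1=r.x1, n1=r.n1, x2=r.x2, n2=r.n2,
                p1_hat=r.p1_hat, p2_hat=r.p2_hat, p_pooled=r.p_pooled,
                z=r.z, p_value=r.p_value, degenerate=r.degenerate,
            )
        )
    return out


def write_proportion_report(
    results: Sequence[PropTestResult], path: str | Path
) -> None:
    """TSV: rank, x1, n1, x2, n2, z, p_value, stars (counts made auditable)."""
    with open(path, "w") as fh:
        fh.write("rank\tx1\tn1\tx2\tn2\tz\tp_value\tstars\n")
        for r in results:
            fh.write(
                f"{r.rank}\t{r.x1}\t{r.n1}\t{r.x2}\t{r.n2}"
                f"\t{r.z:.6g}\t{r.p_value:.6g}\t{r.stars}\n"
            )
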