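"""Taxon-KO correlation links and the KO-density score for KEGG modules.

A taxon is linked to a KO when their abundances are significantly rank
correlated (|rho| > rho_min, BH q < q_max, the family being all taxon x KO
pairs tested together).  A taxon's association with a KEGG module is then
the *density*: the fraction of the module's KOs linked to that taxon,

    density(taxon, module) = |linked KOs in module| / |KOs in module|,

which weights the cross edges of the split graph.  The sign of a link is
ignored when counting: a KO correlated either way with the taxon counts as
correlated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from microsplit.correlation import _t_pvalue
from microsplit.errors import AlignmentError, ValidationError
from microsplit.io_model import AbundanceMatrix, ModuleMap


@dataclass(frozen=True)
class TaxonKOLink:
    """A retained taxon-KO correlation."""

    taxon: str
    ko: str
    rho: float
    p: float
    q: float


@dataclass(frozen=True)
class DensityAssociation:
    """One taxon-module association scored by KO density."""

    taxon: str
    module_id: str
    correlated_kos: frozenset[str]
    module_size: int
    density: float

    def __post_init__(self) -> None:
        if self.module_size < 1:
            raise ValidationError("module_size must be >= 1")
        if len(self.correlated_kos) > self.module_size:
            raise ValidationError("more correlated KOs than module members")

    @property
    def density_exact(self) -> Fraction:
        return Fraction(len(self.correlated_kos), self.module_size)

    @property
    def density_display(self) -> float:
        """Density rounded to 2 decimals, the table display convention."""
        return round(self.density, 2)


def taxon_ko_links(
    taxa: AbundanceMatrix,
    kos: AbundanceMatrix,
    samples: Optional[Iterable[str]] = None,
    rho_min: float = 0.6,
    q_max: float = 0.05,
) -> list[TaxonKOLink]:
    """Significant Spearman links between every taxon and every KO.

    Both tables are aligned on the sample subset by label; a mismatch in
    sample sets raises :class:`AlignmentError` listing the offenders.  BH
    adjustment runs over all taxon x KO pairs tested in this call; pairs
    involving a constant feature are excluded from the family.  Only links
    passing ``|rho| > rho_min`` and ``q < q_max`` are returned.
    """
    if samples is None:
        t_set, k_set = set(taxa.sample_ids), set(kos.sample_ids)
        if t_set != k_set:
            raise AlignmentError(
                f"sample sets differ: only-taxa={sorted(t_set - k_set)}, "
                f"only-kos={sorted(k_set - t_set)}"
            )
        samples = list(taxa.sample_ids)
    else:
        samples = list(samples)
        miss_t = [s for s in samples if s not in taxa.sample_ids]
        miss_k = [s for s in samples if s not in kos.sample_ids]
        if miss_t or miss_k:
            raise AlignmentError(
                f"samples missing from tables: taxa={miss_t}, kos={miss_k}"
            )
    t = taxa.subset_samples(samples)
    k = kos.subset_samples(samples)
    n = t.n_samples
    if n < 4:
        raise ValidationError(f"need >= 4 samples, got {n}")

    rt = np.apply_along_axis(stats.rankdata, 0, t.values)
    rk = np.apply_along_axis(stats.rankdata, 0, k.values)
    st, sk = rt.std(axis=0), rk.std(axis=0)
    zt = (rt - rt.mean(axis=0)) / np.where(st == 0, 1.0, st)
    zk = (rk - rk.mean(axis=0)) / np.where(sk == 0, 1.0, sk)
    rho = (zt.T @ zk) / n  # taxa x kos
    rho[st == 0, :] = math.nan
    rho[:, sk == 0] = math.nan
    rho = np.clip(rho, -1.0, 1.0)

    flat = rho.ravel()
    valid = ~np.isnan(flat)
    pvals = np.full(flat.shape, math.nan)
    pvals[valid] = _t_pvalue(flat[valid], n)
    qvals = np.full(flat.shape, math.nan)
    if valid.any():
        qvals[valid] = multipletests(pvals[valid], method="fdr_bh")[1]

    links: list[TaxonKOLink] = []
    n_kos = k.n_features
    for idx in np.nonzero(valid)[0]:
        r = flat[idx]
        if abs(r) > rho_min and qvals[idx] < q_max:
            i, j = divmod(int(idx), n_kos)
            links.append(
                TaxonKOLink(t.feature_ids[i], k.feature_ids[j], float(r),
                            float(pvals[idx]), float(qvals[idx]))
            )
    links.sort(key=lambda l: (l.taxon, l.ko))
    return links


def module_density(
    links: Sequence[TaxonKOLink],
    module_map: ModuleMap,
    taxon: str,
    module_id: str,
) -> DensityAssociation:
    """Density of one (taxon, module) pair: linked module KOs / module size."""
    if module_id not in module_map:
        raise ValidationError(f"module {module_id!r} not in module map")
    members = module_map[module_id]
    linked = frozenset(l.ko for l in links if l.taxon == taxon and l.ko in members)
    return DensityAssociation(
        taxon=taxon,
        module_id=module_id,
        correlated_kos=linked,
        module_size=len(members),
        density=len(linked) / len(members),
    )


def all_densities(
    links: Sequence[TaxonKOLink],
    module_map: ModuleMap,
    density_min: float = 0.6,
    *,
    cmp: str = "ge",
) -> list[DensityAssociation]:
    """All (taxon, module) associations passing the density threshold.

    ``cmp`` selects the boundary rule: ``"ge"`` keeps density == density_min
    (default — printed association tables include densities sitting exactly
    on the threshold), ``"gt"`` is strict.  Pairs with no linked KOs are
    omitted regardless.
    """
    if cmp not in ("gt", "ge"):
        raise ValueError(f"cmp must be 'gt' or 'ge', got {cmp!r}")
    if not (0.0 <= density_min <= 1.0):
        raise ValueError(f"density_min must be in [0, 1], got {density_min}")
    taxa = sorted({l.taxon for l in links})
    out: list[DensityAssociation] = []
    for taxon in taxa:
        for module_id in sorted(module_map):
            d = module_density(links, module_map, taxon, module_id)
            if not d.correlated_kos:
                continue
            keep = d.density > density_min if cmp == "gt" else d.density >= density_min
            if keep:
                out.append(d)
    return out


def write_links_tsv(links: Sequence[TaxonKOLink], path: str | Path) -> None:
    df = pd.DataFrame(
        [(l.taxon, l.ko, l.rho, l.p, l.q) for l in links],
        columns=["taxon", "ko", "rho", "p", "q"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_links_tsv(path: str | Path) -> list[TaxonKOLink]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        TaxonKOLink(str(r.taxon), str(r.ko), float(r.rho), float(r.p), float(r.q))
        for r in df.itertuples(index=False)
    ]


def write_densities_tsv(dens: Sequence[DensityAssociation], path: str | Path) -> None:
    """TSV: taxon, module, ko_list (semicolon-joined), module_size, density."""
    df = pd.DataFrame(
        [
            (d.taxon, d.module_id, ";".join(sorted(d.correlated_kos)),
             d.module_size, d.density)
            for d in dens
        ],
        columns=["taxon", "module", "ko_list", "module_size", "density"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_densities_tsv(path: str | Path) -> list[DensityAssociation]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        kos = frozenset(str(r.ko_list).split(";")) if str(r.ko_list) else frozenset()
        out.append(
            DensityAssociation(str(r.taxon), str(r.module), kos,
                               int(r.module_size), float(r.density))
        )
    return out
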