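"""Synthetic microbiome datasets with planted, recoverable structure.

The generator emulates the statistical shape the pipeline assumes: taxon
abundances are log-normal, with planted blocks of taxa loading on a shared
latent factor (so block pairs are rank-correlated with a tunable strength);
each planted taxon->module coupling drives a chosen fraction of that
module's KOs as a monotone function of the taxon's abundance, so Spearman
recovery is exact in the noiseless limit.  Group sizes default to the
mucosal-tissue / stool study design (36 CDT, 10 CDS, 9 HCS samples).  A
machine-readable ground-truth record lists every planted edge and coupling
so downstream tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from microsplit.errors import ConfigError
from microsplit.io_model import (
    AbundanceMatrix,
    GroupAssignment,
    Lineage,
    ModuleMap,
    parse_lineage,
    write_abundance_table,
    write_group_assignment,
    write_lineage_table,
    write_module_map,
)

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")


@dataclass(frozen=True)
class PlantedBlock:
    """A set of taxa loading on one shared latent factor with the given strength."""

    taxa: tuple[str, ...]
    strength: float


@dataclass(frozen=True)
class PlantedCoupling:
    """A taxon driving a fraction of one module's KOs."""

    taxon: str
    module: str
    fraction: float


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic dataset.

    ``n_samples_per_group`` may be a single count or a per-group mapping;
    the default mirrors a mucosal-tissue vs. stool case-control design.
    ``noise_sd`` is the standard deviation of the additive Gaussian noise on
    the log scale, applied both to taxa and to driven KOs.
    """

    n_samples_per_group: Union[int, Mapping[str, int]] = None  # type: ignore[assignment]
    groups: tuple[str, ...] = ("CDT", "CDS", "HCS")
    n_taxa: int = 20
    planted_blocks: tuple[PlantedBlock, ...] = ()
    n_kos: int = 60
    n_modules: int = 10
    planted_couplings: tuple[PlantedCoupling, ...] = ()
    noise_sd: float = 0.1
    seed: int = 0
    lineage_plan: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if self.n_samples_per_group is None:
            object.__setattr__(
                self, "n_samples_per_group", {"CDT": 36, "CDS": 10, "HCS": 9}
            )

    # -- derived layout ----------------------------------------------------

    def taxon_labels(self) -> list[str]:
        return [f"OTU_{i + 1:04d}" for i in range(self.n_taxa)]

    def ko_labels(self) -> list[str]:
        return [f"K{i + 1:05d}" for i in range(self.n_kos)]

    def module_labels(self) -> list[str]:
        return [f"M{i + 1:05d}" for i in range(self.n_modules)]

    def module_partition(self) -> dict[str, list[str]]:
        """KOs dealt round-robin into modules, sizes as even as possible."""
        kos = self.ko_labels()
        mods = self.module_labels()
        out: dict[str, list[str]] = {m: [] for m in mods}
        for i, ko in enumerate(kos):
            out[mods[i % len(mods)]].append(ko)
        return out

    def samples_per_group(self) -> dict[str, int]:
        if isinstance(self.n_samples_per_group, int):
            return {g: self.n_samples_per_group for g in self.groups}
        return {g: int(self.n_samples_per_group[g]) for g in self.groups}

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ConfigError("need at least 2 taxa")
        if self.n_kos < 1 or self.n_modules < 1:
            raise ConfigError("need at least 1 KO and 1 module")
        if self.n_modules > self.n_kos:
            raise ConfigError(
                f"{self.n_modules} modules cannot partition {self.n_kos} KOs"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for g, n in self.samples_per_group().items():
            if n < 4:
                raise ConfigError(f"group {g!r} needs >= 4 samples, has {n}")
        taxa = set(self.taxon_labels())
        for b in self.planted_blocks:
            if not (0.0 <= b.strength <= 1.0):
                raise ConfigError(f"block strength {b.strength} outside [0, 1]")
            unknown = set(b.taxa) - taxa
            if unknown:
                raise ConfigError(f"block names unknown taxa: {sorted(unknown)}")
            if len(set(b.taxa)) < 2:
                raise ConfigError("a planted block needs >= 2 distinct taxa")
        partition = self.module_partition()
        for c in self.planted_couplings:
            if c.taxon not in taxa:
                raise ConfigError(f"coupling names unknown taxon {c.taxon!r}")
            if c.module not in partition:
                raise ConfigError(f"coupling names unknown module {c.module!r}")
            if not (0.0 <= c.fraction <= 1.0):
                raise ConfigError(f"coupling fraction {c.fraction} outside [0, 1]")
            size = len(partition[c.module])
            k = c.fraction * size
            if abs(k - round(k)) > 1e-9 or (c.fraction > 0 and round(k) < 1):
                raise ConfigError(
                    f"coupling fraction {c.fraction} is not representable on "
                    f"module {c.module} of {size} KOs: {c.fraction} x {size} = "
                    f"{k:.4g} is not a whole number of KOs"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Machine-readable record of everything planted in a dataset."""

    planted_edges: tuple[tuple[str, str], ...]
    couplings: tuple[tuple[str, str, tuple[str, ...], float], ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_edges": [list(e) for e in self.planted_edges],
                "couplings": [
                    {"taxon": t, "module": m, "driven_kos": list(kos), "fraction": f}
                    for t, m, kos, f in self.couplings
                ],
            },
            indent=2,
        )


@dataclass
class SynthData:
    taxa: AbundanceMatrix
    kos: AbundanceMatrix
    module_map: ModuleMap
    lineages: dict[str, Lineage]
    groups: GroupAssignment
    truth: GroundTruth
    config: SynthConfig


def _auto_lineages(cfg: SynthConfig) -> dict[str, Lineage]:
    """Default lineage plan: each block shares a family (and order, class).

    Taxa outside every block get unique families; phyla cycle over a small
    set so higher-rank ancestors are shared across unrelated taxa, as in a
    real community.
    """
    block_of: dict[str, int] = {}
    for i, b in enumerate(cfg.planted_blocks):
        for t in b.taxa:
            block_of.setdefault(t, i)
    out: dict[str, Lineage] = {}
    for j, taxon in enumerate(cfg.taxon_labels()):
        if taxon in block_of:
            i = block_of[taxon]
            phylum = _PHYLA[i % len(_PHYLA)]
            cls, order, family = f"BlockClass{i + 1}", f"BlockOrder{i + 1}", f"BlockFam{i + 1}"
        else:
            phylum = _PHYLA[j % len(_PHYLA)]
            cls, order, family = f"SoloClass{j + 1}", f"SoloOrder{j + 1}", f"SoloFam{j + 1}"
        out[taxon] = Lineage(
            {
                "kingdom": "Bacteria",
                "phylum": phylum,
                "class": cls,
                "order": order,
                "family": family,
                "genus": f"Genus{j + 1}",
            }
        )
    return out


def generate(cfg: SynthConfig) -> SynthData:
    """Generate one dataset; bit-identical outputs for identical configs.

    Taxon log-abundance per sample is the planted-factor mixture plus unit
    idiosyncratic noise (variance complementary to the squared loadings)
    plus ``noise_sd`` Gaussian noise; abundances are its exponential.  Each
    driven KO is its driving taxon's log-abundance plus ``noise_sd`` noise
    (a strictly monotone link up to noise); undriven KOs are independent
    log-normals.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    taxa_labels = cfg.taxon_labels()
    ko_labels = cfg.ko_labels()
    partition = cfg.module_partition()
    per_group = cfg.samples_per_group()

    sample_ids: list[str] = []
    group_map: dict[str, str] = {}
    for g in cfg.groups:
        for i in range(per_group[g]):
            sid = f"{g}_{i + 1:03d}"
            sample_ids.append(sid)
            group_map[sid] = g
    n_total = len(sample_ids)

    # loadings per taxon: list of (block index, strength)
    loadings: dict[str, list[tuple[int, float]]] = {t: [] for t in taxa_labels}
    for bi, b in enumerate(cfg.planted_blocks):
        for t in set(b.taxa):
            loadings[t].append((bi, b.strength))

    factors = rng.standard_normal((n_total, len(cfg.planted_blocks)))
    idio = rng.standard_normal((n_total, cfg.n_taxa))
    extra = rng.standard_normal((n_total, cfg.n_taxa))

    log_taxa = np.empty((n_total, cfg.n_taxa))
    for j, t in enumerate(taxa_labels):
        shared = np.zeros(n_total)
        s2 = 0.0
        for bi, s in loadings[t]:
            shared += s * factors[:, bi]
            s2 += s * s
        resid = np.sqrt(max(0.0, 1.0 - s2))
        log_taxa[:, j] = shared + resid * idio[:, j] + cfg.noise_sd * extra[:, j]

    # KO layer: resolve driven sets first (deterministic: sorted module KOs)
    driven_by: dict[str, str] = {}
    couplings_resolved: list[tuple[str, str, tuple[str, ...], float]] = []
    for c in cfg.planted_couplings:
        members = sorted(partition[c.module])
        k = int(round(c.fraction * len(members)))
        driven = tuple(members[:k])
        couplings_resolved.append((c.taxon, c.module, driven, c.fraction))
        for ko in driven:
            driven_by.setdefault(ko, c.taxon)  # first coupling wins on overlap

    ko_noise = rng.standard_normal((n_total, cfg.n_kos))
    log_kos = np.empty((n_total, cfg.n_kos))
    taxon_index = {t: j for j, t in enumerate(taxa_labels)}
    for j, ko in enumerate(ko_labels):
        if ko in driven_by:
            src = taxon_index[driven_by[ko]]
            log_kos[:, j] = log_taxa[:, src] + cfg.noise_sd * ko_noise[:, j]
        else:
            log_kos[:, j] = ko_noise[:, j]

    taxa_df = pd.DataFrame(np.exp(log_taxa), index=sample_ids, columns=taxa_labels)
    kos_df = pd.DataFrame(np.exp(log_kos), index=sample_ids, columns=ko_labels)

    if cfg.lineage_plan is not None:
        lineages = {t: parse_lineage(s) for t, s in cfg.lineage_plan.items()}
    else:
        lineages = _auto_lineages(cfg)

    planted_edges: list[tuple[str, str]] = []
    seen = set()
    for b in cfg.planted_blocks:
        if b.strength <= 0:
            continue
        members = sorted(set(b.taxa))
        for i, a in enumerate(members):
            for bb in members[i + 1:]:
                if (a, bb) not in seen:
                    seen.add((a, bb))
                    planted_edges.append((a, bb))

    return SynthData(
        taxa=AbundanceMatrix(taxa_df, "taxon"),
        kos=AbundanceMatrix(kos_df, "ko"),
        module_map=ModuleMap({m: frozenset(kos) for m, kos in partition.items()}),
        lineages=lineages,
        groups=GroupAssignment(group_map),
        truth=GroundTruth(tuple(planted_edges), tuple(couplings_resolved)),
        config=cfg,
    )


def demo_config(seed: int = 0, *, n_samples_per_group: Union[int, Mapping[str, int], None] = None) -> SynthConfig:
    """A small configuration with recoverable planted structure.

    One 4-taxon block and one 3-taxon block at loading 0.95, each block's
    lead taxon driving 80% of one 5-KO module and 60% of another — the kind
    of signal the pipeline is built to find.
    """
    cfg = SynthConfig(n_samples_per_group=n_samples_per_group, seed=seed)
    taxa = cfg.taxon_labels()
    mods = cfg.module_labels()
    blocks = (
        PlantedBlock(tuple(taxa[0:4]), 0.95),
        PlantedBlock(tuple(taxa[4:7]), 0.95),
    )
    couplings = (
        PlantedCoupling(taxa[0], mods[0], 0.8),
        PlantedCoupling(taxa[1], mods[0], 0.8),
        PlantedCoupling(taxa[4], mods[1], 0.6),
    )
    return SynthConfig(
        n_samples_per_group=cfg.n_samples_per_group,
        groups=cfg.groups,
        n_taxa=cfg.n_taxa,
        planted_blocks=blocks,
        n_kos=50,
        n_modules=10,
        planted_couplings=couplings,
        noise_sd=0.1,
        seed=seed,
    )


def write_synthetic_dataset(data: SynthData, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact TSV formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxa": outdir / "taxa_abundance.tsv",
        "kos": outdir / "ko_abundance.tsv",
        "modules": outdir / "module_map.tsv",
        "lineages": outdir / "lineages.tsv",
        "groups": outdir / "groups.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_abundance_table(data.taxa, paths["taxa"])
    write_abundance_table(data.kos, paths["kos"])
    write_module_map(data.module_map, paths["modules"])
    write_lineage_table(data.lineages, paths["lineages"])
    write_group_assignment(data.groups, paths["groups"])
    paths["ground_truth"].write_text(data.truth.to_json())
    return paths
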