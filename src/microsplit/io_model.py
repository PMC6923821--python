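"""Core domain types and TSV/CSV readers and writers.

Abundance tables are held as pandas DataFrames (samples x features) wrapped in
:class:`AbundanceMatrix`; taxonomy is carried as Greengenes-style lineage
strings parsed into :class:`Lineage` records; KO-to-module membership comes
from a static two-column table standing in for a live KEGG lookup.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from microsplit.errors import ParseError, ValidationError

#: Fixed taxonomic rank order, kingdom -> species.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Greengenes single-letter prefixes, aligned with RANKS.
RANK_PREFIXES: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s")

_PREFIX_TO_RANK = {p: r for p, r in zip(RANK_PREFIXES, RANKS)}
_RANK_TO_PREFIX = {r: p for p, r in zip(RANK_PREFIXES, RANKS)}

#: Sentinel feature label for taxa lacking the aggregation rank.
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic assignment parsed from a Greengenes-style string.

    A rank without an assignment (an empty ``g__`` payload, or a missing
    field altogether) is recorded as absent (``None``), never as an
    empty-string taxon.
    """

    ranks: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rank, name in self.ranks.items():
            if rank not in RANKS:
                raise ValidationError(f"unknown taxonomic rank {rank!r}")
            if not name:
                raise ValidationError(
                    f"empty taxon name for rank {rank!r}; omit the rank instead"
                )
        # freeze into a plain dict in canonical rank order
        object.__setattr__(
            self,
            "ranks",
            {r: self.ranks[r] for r in RANKS if r in self.ranks},
        )

    def get(self, rank: str) -> Optional[str]:
        if rank not in RANKS:
            raise ValueError(f"unknown taxonomic rank {rank!r}")
        return self.ranks.get(rank)

    def to_string(self) -> str:
        """Serialize back to Greengenes form; absent ranks get empty payloads."""
        parts = []
        for rank, prefix in zip(RANKS, RANK_PREFIXES):
            name = self.ranks.get(rank, "")
            parts.append(f"{prefix}__{name}")
        return "; ".join(parts)

    def truncate(self, rank: str) -> "Lineage":
        """Lineage restricted to ranks at or above ``rank``."""
        if rank not in RANKS:
            raise ValueError(f"unknown taxonomic rank {rank!r}")
        cut = RANKS.index(rank)
        return Lineage({r: v for r, v in self.ranks.items() if RANKS.index(r) <= cut})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lineage):
            return NotImplemented
        return dict(self.ranks) == dict(other.ranks)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.ranks.items())))


def parse_lineage(s: str) -> Lineage:
    """Parse a Greengenes-style lineage string.

    Accepts e.g. ``"k__Bacteria; p__Bacteroidetes; f__Bacteroidaceae"``.
    Empty payloads (``"g__"``) become absent ranks; whitespace around fields
    is ignored.  An unknown rank prefix raises :class:`ParseError`.
    """
    ranks: dict[str, str] = {}
    for raw in s.split(";"):
        token = raw.strip()
        if not token:
            continue
        if len(token) < 3 or token[1:3] != "__" or token[0] not in _PREFIX_TO_RANK:
            raise ParseError(f"unrecognized lineage field {token!r} in {s!r}")
        rank = _PREFIX_TO_RANK[token[0]]
        name = token[3:].strip()
        if name:
            ranks[rank] = name
    return Lineage(ranks)


@dataclass
class AbundanceMatrix:
    """Samples x features table of non-negative abundances.

    ``data`` is indexed by sample id with one column per feature;
    ``feature_kind`` is ``"taxon"`` or ``"ko"``.  Values may be counts or
    relative abundances — correlation downstream is rank-based either way.
    """

    data: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in ("taxon", "ko"):
            raise ValidationError(
                f"feature_kind must be 'taxon' or 'ko', got {self.feature_kind!r}"
            )
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance table contains non-numeric values")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"NaN abundance at sample {df.index[r]!r}, feature {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[r]!r}, "
                f"feature {df.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: Iterable[str]) -> "AbundanceMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return AbundanceMatrix(self.data.loc[samples], self.feature_kind)

    def to_relative(self) -> "AbundanceMatrix":
        """Per-sample relative abundance (each row sums to 1).

        Rows summing to zero are left as zeros.
        """
        sums = self.data.sum(axis=1)
        out = self.data.div(sums.replace(0.0, 1.0), axis=0)
        return AbundanceMatrix(out, self.feature_kind)


@dataclass(frozen=True)
class ModuleMap:
    """KEGG module membership: module id -> set of KO ids."""

    modules: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        frozen = {}
        for mod, kos in self.modules.items():
            if not mod:
                raise ValidationError("empty module id")
            kos = frozenset(kos)
            if not kos:
                raise ValidationError(f"module {mod!r} has no KOs")
            if any(not k for k in kos):
                raise ValidationError(f"module {mod!r} contains an empty KO id")
            frozen[mod] = kos
        object.__setattr__(self, "modules", frozen)

    def __getitem__(self, module_id: str) -> frozenset[str]:
        return self.modules[module_id]

    def __contains__(self, module_id: str) -> bool:
        return module_id in self.modules

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def items(self):
        return self.modules.items()


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping sample id -> group label (e.g. CDT / CDS / HCS)."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        for sample, group in self.assignments.items():
            if not group:
                raise ValidationError(f"sample {sample!r} has an empty group label")
        object.__setattr__(self, "assignments", dict(self.assignments))

    def group_of(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g)
        return list(seen)

    def __len__(self) -> int:
        return len(self.assignments)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, delimiter: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        # sniff: tab wins if present in the header line, else comma
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)


def read_abundance_table(
    path: str | Path,
    feature_kind: str,
    *,
    orientation: str = "features_as_rows",
    delimiter: Optional[str] = None,
    normalize: bool = False,
) -> AbundanceMatrix:
    """Read a TSV/CSV abundance table into an :class:`AbundanceMatrix`.

    The default orientation follows the QIIME/PICRUSt convention of features
    as rows and samples as columns; pass ``orientation="samples_as_rows"``
    for the transpose.  ``normalize=True`` converts to per-sample relative
    abundances after reading.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path, delimiter)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"non-numeric abundance at row {row!r}, column {col!r} in {path}"
            )
        numeric[col] = converted
    if numeric.isna().to_numpy().any():
        raise ValidationError(f"missing abundance values in {path}")
    if orientation == "features_as_rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str).rename(None)
    numeric.columns = numeric.columns.astype(str).rename(None)
    m = AbundanceMatrix(numeric, feature_kind)
    return m.to_relative() if normalize else m


def write_abundance_table(
    m: AbundanceMatrix,
    path: str | Path,
    *,
    orientation: str = "features_as_rows",
    delimiter: str = "\t",
) -> None:
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = m.data.T if orientation == "features_as_rows" else m.data
    label = "feature_id" if orientation == "features_as_rows" else "sample_id"
    df.to_csv(path, sep=delimiter, index_label=label)


def read_module_map(path: str | Path, *, delimiter: str = "\t") -> ModuleMap:
    """Read a two-column (module_id, ko_id) TSV; duplicate rows are collapsed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    modules: dict[str, set[str]] = collections.defaultdict(set)
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            mod, ko = fields[0], fields[1]
            if lineno == 1 and mod.lower() in ("module_id", "module"):
                continue  # optional header
            modules[mod].add(ko)
            n_rows += 1
    if n_rows == 0:
        raise ValidationError(f"module map {path} contains no entries")
    return ModuleMap(modules)


def write_module_map(mm: ModuleMap, path: str | Path, *, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"module_id{delimiter}ko_id\n")
        for mod in sorted(mm):
            for ko in sorted(mm[mod]):
                fh.write(f"{mod}{delimiter}{ko}\n")


def read_lineage_table(path: str | Path, *, delimiter: str = "\t") -> dict[str, Lineage]:
    """Read a two-column (feature_id, lineage string) TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            feature, lineage = fields[0].strip(), fields[1].strip()
            if lineno == 1 and feature.lower() in ("feature_id", "otu_id", "#otu id"):
                continue
            if feature in out:
                raise ValidationError(f"duplicate feature {feature!r} in {path}")
            out[feature] = parse_lineage(lineage)
    return out


def write_lineage_table(
    lineages: Mapping[str, Lineage], path: str | Path, *, delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"feature_id{delimiter}lineage\n")
        for feature in sorted(lineages):
            fh.write(f"{feature}{delimiter}{lineages[feature].to_string()}\n")


def read_group_assignment(path: str | Path, *, delimiter: str = "\t") -> GroupAssignment:
    """Read a two-column (sample_id, group) TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            sample, group = fields[0], fields[1]
            if lineno == 1 and sample.lower() in ("sample_id", "sample", "#sampleid"):
                continue
            if sample in out:
                raise ValidationError(f"duplicate sample {sample!r} in {path}")
            out[sample] = group
    return GroupAssignment(out)


def write_group_assignment(
    groups: GroupAssignment, path: str | Path, *, delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"sample_id{delimiter}group\n")
        for sample, group in groups.assignments.items():
            fh.write(f"{sample}{delimiter}{group}\n")


# ---------------------------------------------------------------------------
# taxonomy aggregation


def aggregate_to_rank(
    m: AbundanceMatrix,
    lineages: Mapping[str, Lineage],
    rank: str,
    *,
    include_unassigned: bool = True,
) -> AbundanceMatrix:
    """Collapse a taxon table to a taxonomic rank by summing member abundances.

    Output feature labels carry the Greengenes prefix of the rank, e.g.
    ``f__Bacteroidaceae``.  Features lacking the rank are pooled under the
    ``unassigned`` sentinel (dropped when ``include_unassigned`` is false);
    downstream ancestor tests exclude that sentinel since it cannot witness
    a shared lineage.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomic rank {rank!r}")
    if m.feature_kind != "taxon":
        raise ValidationError("aggregate_to_rank applies to taxon tables only")
    missing = [f for f in m.feature_ids if f not in lineages]
    if missing:
        raise ValidationError(f"features without lineage: {missing[:5]}")
    prefix = _RANK_TO_PREFIX[rank]
    labels = []
    for f in m.feature_ids:
        name = lineages[f].get(rank)
        labels.append(f"{prefix}__{name}" if name else UNASSIGNED)
    grouped = m.data.T.groupby(pd.Index(labels, name="feature_id")).sum().T
    if not include_unassigned and UNASSIGNED in grouped.columns:
        grouped = grouped.drop(columns=[UNASSIGNED])
    return AbundanceMatrix(grouped, "taxon")


def collapse_lineages(
    lineages: Mapping[str, Lineage], rank: str
) -> dict[str, Lineage]:
    """Lineages for the features produced by :func:`aggregate_to_rank`.

    Each aggregated label maps to the lineage truncated at ``rank``; if member
    features disagree on ancestor ranks the most common full assignment wins.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomic rank {rank!r}")
    prefix = _RANK_TO_PREFIX[rank]
    votes: dict[str, collections.Counter] = collections.defaultdict(collections.Counter)
    for lin in lineages.values():
        name = lin.get(rank)
        if name is None:
            continue
        votes[f"{prefix}__{name}"][lin.truncate(rank)] += 1
    return {label: counter.most_common(1)[0][0] for label, counter in votes.items()}
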