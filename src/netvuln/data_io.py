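"""Readers, writers and run configuration.

All tabular formats are tab-separated text; lines starting with ``#`` are
comments.  Expression matrices are features x samples on log2 scale and are
carried in memory as :class:`pandas.DataFrame` (index = feature IDs,
columns = sample IDs).  Sample groups are a :class:`pandas.Series` mapping
sample ID to ``"sensitive"`` or ``"resistant"``.  Gene and miRNA IDs are
opaque case-sensitive strings; no symbol normalization is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("sensitive", "resistant")

CLINICAL_COLUMNS = ("pfs_time", "pfs_event", "os_time", "os_event")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

class RegulatoryNetwork:
    """Bipartite miRNA -> mRNA regulatory edge list.

    Edges are stored deduplicated in first-seen order.  The two node
    partitions are inferred from edge position (first member = miRNA) and
    must be disjoint.
    """

    __slots__ = ("edges", "mirnas", "mrnas", "_targets", "_in_degree")

    def __init__(self, edges: Iterable[tuple[str, str]]):
        seen: set[tuple[str, str]] = set()
        ordered: list[tuple[str, str]] = []
        mirnas: dict[str, None] = {}
        mrnas: dict[str, None] = {}
        for m, g in edges:
            e = (str(m), str(g))
            if e in seen:
                continue
            seen.add(e)
            ordered.append(e)
            mirnas.setdefault(e[0])
            mrnas.setdefault(e[1])
        overlap = set(mirnas) & set(mrnas)
        if overlap:
            raise FormatError(
                "ID(s) appear in both the miRNA and mRNA partitions: "
                + ", ".join(sorted(overlap)[:5])
            )
        self.edges: tuple[tuple[str, str], ...] = tuple(ordered)
        self.mirnas: tuple[str, ...] = tuple(mirnas)
        self.mrnas: tuple[str, ...] = tuple(mrnas)
        self._targets: dict[str, tuple[str, ...]] | None = None
        self._in_degree: dict[str, int] | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets(self, mirna: str) -> tuple[str, ...]:
        """Targets of one miRNA, in edge order."""
        if self._targets is None:
            t: dict[str, list[str]] = {m: [] for m in self.mirnas}
            for m, g in self.edges:
                t[m].append(g)
            self._targets = {m: tuple(v) for m, v in t.items()}
        return self._targets.get(mirna, ())

    def in_degree(self) -> dict[str, int]:
        """Number of distinct regulating miRNAs per mRNA."""
        if self._in_degree is None:
            d: dict[str, int] = {g: 0 for g in self.mrnas}
            for _, g in self.edges:
                d[g] += 1
            self._in_degree = d
        return self._in_degree

    def degree(self, mirna: str) -> int:
        return len(self.targets(mirna))

    def to_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge list as integer index arrays (miRNA index, mRNA index),
        indices into :attr:`mirnas` / :attr:`mrnas`."""
        mi = {m: i for i, m in enumerate(self.mirnas)}
        gi = {g: i for i, g in enumerate(self.mrnas)}
        a = np.fromiter((mi[m] for m, _ in self.edges), dtype=np.int64)
        b = np.fromiter((gi[g] for _, g in self.edges), dtype=np.int64)
        return a, b

    def __eq__(self, other) -> bool:
        return isinstance(other, RegulatoryNetwork) and set(self.edges) == set(other.edges)

    def __hash__(self):
        return hash(frozenset(self.edges))

    def __repr__(self) -> str:
        return (f"RegulatoryNetwork({self.n_edges} edges, "
                f"{len(self.mirnas)} miRNAs, {len(self.mrnas)} mRNAs)")


@dataclass
class GeneSetCollection:
    """Named gene sets: set_id -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self):
        for sid, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {sid!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {sid!r} has duplicate members")

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for _, (_d, m) in self.sets.items():
            out.update(m)
        return out

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class RunConfig:
    """All thresholds and knobs of the pipeline, with the defaults used
    throughout: fold-change bounds 1.5 / 0.67 and FDR 0.05 for differential
    expression, permutation alpha 0.01 for the NSR statistic, top-10%
    hub/bottleneck rule, upper-quartile survival split, and enrichment
    cutoffs adjusted p < 0.05 with fold enrichment > 1.5.
    """

    fc_hi: float = 1.5
    fc_lo: float = 0.67
    de_alpha: float = 0.05
    nsr_alpha: float = 0.01
    hub_fraction: float = 0.10
    quartile: float = 0.75
    enrich_alpha: float = 0.05
    enrich_fold: float = 1.5
    seed: int = 0
    n_perm: int = 1000
    nsr_method: str = "rewire"
    paths: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.fc_lo < 1 < self.fc_hi):
            raise ParameterError(
                f"require 0 < fc_lo < 1 < fc_hi, got fc_lo={self.fc_lo}, fc_hi={self.fc_hi}"
            )
        for name in ("de_alpha", "nsr_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ParameterError(f"{name} must be in (0,1), got {v}")
        if not (0 < self.hub_fraction < 1):
            raise ParameterError(f"hub_fraction must be in (0,1), got {self.hub_fraction}")
        if not (0 < self.quartile < 1):
            raise ParameterError(f"quartile must be in (0,1), got {self.quartile}")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be positive")
        if self.nsr_method not in ("rewire", "rank"):
            raise ParameterError(f"nsr_method must be 'rewire' or 'rank', got {self.nsr_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Low-level TSV helpers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a features x samples log2 expression TSV.

    First row: sample IDs (first cell is a corner label and is ignored);
    first column: feature IDs.  Raises :class:`FormatError` on duplicate
    IDs, non-numeric cells, or an empty data section.
    """
    rows = list(_data_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0][1].split("\t")
    sample_ids = header[1:]
    if len(sample_ids) == 0:
        raise FormatError(f"{path}: no sample columns in header")
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    feature_ids: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in rows[1:]:
        cells = line.split("\t")
        fid = cells[0]
        if fid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate feature ID {fid!r}")
        seen.add(fid)
        if len(cells) - 1 != len(sample_ids):
            raise FormatError(
                f"{path}:{lineno}: expected {len(sample_ids)} values, got {len(cells) - 1}"
            )
        row = []
        for j, cell in enumerate(cells[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column "
                    f"{sample_ids[j]!r}"
                ) from None
            if not np.isfinite(v):
                raise FormatError(
                    f"{path}:{lineno}: non-finite value in column {sample_ids[j]!r}"
                )
            row.append(v)
        feature_ids.append(fid)
        values.append(row)
    if not feature_ids:
        raise FormatError(f"{path}: no features (header only)")
    return pd.DataFrame(values, index=feature_ids, columns=sample_ids, dtype=float)


def write_expression(expr: pd.DataFrame, path: str | Path, corner: str = "feature_id") -> None:
    with open(path, "w") as fh:
        fh.write(corner + "\t" + "\t".join(map(str, expr.columns)) + "\n")
        for fid, row in zip(expr.index, expr.to_numpy()):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _first_duplicate(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# Sample groups and clinical table
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, label); labels must be 'sensitive' or
    'resistant' and both groups must be non-empty."""
    ids, labels = [], []
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        if cells[0] == "sample_id":  # optional header
            continue
        if cells[1] not in GROUP_LABELS:
            raise FormatError(
                f"{path}:{lineno}: label {cells[1]!r} not in {GROUP_LABELS}"
            )
        ids.append(cells[0])
        labels.append(cells[1])
    dup = _first_duplicate(ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    s = pd.Series(labels, index=ids, name="group")
    validate_groups(s)
    return s


def validate_groups(groups: pd.Series) -> None:
    counts = groups.value_counts()
    for lab in GROUP_LABELS:
        if counts.get(lab, 0) == 0:
            raise FormatError(f"group {lab!r} is empty")
    extra = set(groups.unique()) - set(GROUP_LABELS)
    if extra:
        raise FormatError(f"unexpected group labels: {sorted(extra)}")


def write_groups(groups: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, lab in groups.items():
            fh.write(f"{sid}\t{lab}\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV with columns sample_id, pfs_time, pfs_event, os_time,
    os_event.  Times are months (>= 0); events are 0/1."""
    rows = list(_data_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0][1].split("\t")
    expected = ["sample_id", *CLINICAL_COLUMNS]
    if header != expected:
        raise FormatError(f"{path}: header must be {expected}, got {header}")
    recs = []
    for lineno, line in rows[1:]:
        cells = line.split("\t")
        if len(cells) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        try:
            rec = [cells[0]] + [float(c) for c in cells[1:]]
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from None
        recs.append(rec)
    df = pd.DataFrame(recs, columns=expected).set_index("sample_id")
    validate_clinical(df)
    return df


def validate_clinical(df: pd.DataFrame) -> None:
    for col in ("pfs_time", "os_time"):
        if (df[col] < 0).any():
            raise FormatError(f"negative value in {col}")
    for col in ("pfs_event", "os_event"):
        if not df[col].isin([0.0, 1.0]).all():
            raise FormatError(f"{col} must be 0/1")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(CLINICAL_COLUMNS) + "\n")
        for sid, row in df.iterrows():
            fh.write(
                f"{sid}\t{float(row['pfs_time'])!r}\t{int(row['pfs_event'])}"
                f"\t{float(row['os_time'])!r}\t{int(row['os_event'])}\n"
            )


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------

def read_network(path: str | Path) -> RegulatoryNetwork:
    """Two-column edge-list TSV (miRNA, target mRNA).  Duplicate edges in
    the file are deduplicated; an ID occurring in both columns is an error."""
    edges = []
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        if cells[0] in ("mirna", "miRNA") and lineno == 1:
            continue
        edges.append((cells[0], cells[1]))
    if not edges:
        raise FormatError(f"{path}: no edges")
    return RegulatoryNetwork(edges)


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tmrna\n")
        for m, g in network.edges:
            fh.write(f"{m}\t{g}\n")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set_id, description, members...) or a one-ID-per-line
    list; a plain list becomes a single set named after the file stem."""
    path = Path(path)
    lines = list(_data_lines(path))
    if not lines:
        raise FormatError(f"{path}: empty file")
    is_gmt = any("\t" in line for _, line in lines)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    if is_gmt:
        for lineno, line in lines:
            cells = line.split("\t")
            if len(cells) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs set_id, description and >=1 member"
                )
            sid, desc, members = cells[0], cells[1], tuple(c for c in cells[2:] if c)
            if not members:
                raise FormatError(f"{path}:{lineno}: empty set {sid!r}")
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set ID {sid!r}")
            sets[sid] = (desc, members)
    else:
        members = tuple(dict.fromkeys(line for _, line in lines))
        sets[path.stem] = (f"list from {path.name}", members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write(sid + "\t" + desc + "\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# Reports and logging
# ---------------------------------------------------------------------------

def write_report(results: Mapping, path: str | Path) -> None:
    """Serialize a (possibly nested) result mapping as pretty JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def configure_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
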