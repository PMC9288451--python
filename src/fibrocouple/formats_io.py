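"""Readers, writers and validated domain containers for every external format.

All tabular formats are plain text (TSV/CSV, MatrixMarket, SIF, GraphML) so a
study can be round-tripped without binary dependencies.  Validation is total:
malformed input raises one of the named exception types below, never a silent
coercion.  Lines starting with ``#`` in TSV/CSV files are treated as comment
headers (the pipeline stamps a config hash there) and skipped on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

MODELS = ("bleomycin", "aav_tgfb1")
ARMS = ("treated", "control")
DEFAULT_DAYS = (3, 7, 14, 21, 28)

RNA_ALPHABET = set("ACGU")
_DNA_OK = set("ACGUT")


# ---------------------------------------------------------------------------
# Named errors
# ---------------------------------------------------------------------------

class FormatsError(ValueError):
    """Base class for all validation failures in this module."""


class MissingFileError(FormatsError):
    pass


class NonNumericCellError(FormatsError):
    pass


class DuplicateIdError(FormatsError):
    pass


class NegativeCountError(FormatsError):
    pass


class UnknownTokenError(FormatsError):
    pass


class UnmatchedContrastError(FormatsError):
    pass


class InvalidAlphabetError(FormatsError):
    pass


class InvalidDayError(FormatsError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDesign:
    """One animal/sample in the two-model longitudinal design."""

    sample_id: str
    model: str          # bleomycin | aav_tgfb1
    arm: str            # treated | control
    day: int            # days post-administration
    animal_id: str

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise UnknownTokenError(f"unknown model {self.model!r}")
        if self.arm not in ARMS:
            raise UnknownTokenError(f"unknown arm {self.arm!r}")
        if self.day <= 0:
            raise InvalidDayError(f"day must be strictly positive, got {self.day}")


class SampleSheet:
    """Validated collection of :class:`SampleDesign` rows.

    Enforces unique sample ids, a configurable day set, and that every treated
    (model, day) group has a same-day control group of the same model —
    contrasts are always paired against the respective same-day controls.
    """

    def __init__(self, designs: Sequence[SampleDesign],
                 days: Iterable[int] = DEFAULT_DAYS):
        self.days = tuple(sorted(set(int(d) for d in days)))
        if any(d <= 0 for d in self.days):
            raise InvalidDayError("day set must be strictly positive")
        self.designs = list(designs)
        seen: set[str] = set()
        for d in self.designs:
            if d.sample_id in seen:
                raise DuplicateIdError(f"duplicate sample_id {d.sample_id!r}")
            seen.add(d.sample_id)
            if d.day not in self.days:
                raise InvalidDayError(
                    f"sample {d.sample_id}: day {d.day} not in allowed set {self.days}")
        # every treated group needs same-day controls of the same model
        groups = {(d.model, d.arm, d.day) for d in self.designs}
        for model, arm, day in sorted(groups):
            if arm == "treated" and (model, "control", day) not in groups:
                raise UnmatchedContrastError(
                    f"treated group ({model}, day {day}) has no same-day control")

    def __len__(self) -> int:
        return len(self.designs)

    def __iter__(self):
        return iter(self.designs)

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.designs]

    def group(self, model: str, arm: str, day: int) -> list[str]:
        return [d.sample_id for d in self.designs
                if d.model == model and d.arm == arm and d.day == day]

    def smallest_group_size(self) -> int:
        sizes = {}
        for d in self.designs:
            key = (d.model, d.arm, d.day)
            sizes[key] = sizes.get(key, 0) + 1
        return min(sizes.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.sample_id, d.model, d.arm, d.day, d.animal_id) for d in self.designs],
            columns=["sample_id", "model", "arm", "day", "animal_id"],
        )


@dataclass
class ExpressionMatrix:
    """Features × samples expression grid, typed by molecule kind and scale.

    ``values`` is a pandas DataFrame indexed by feature id with sample-id
    columns.  ``scale`` is ``counts`` (non-negative) or ``log_cpm``.
    """

    values: pd.DataFrame
    kind: str            # mrna | mirna
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("mrna", "mirna"):
            raise UnknownTokenError(f"unknown matrix kind {self.kind!r}")
        if self.scale not in ("counts", "log_cpm"):
            raise UnknownTokenError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DuplicateIdError(f"duplicate feature id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DuplicateIdError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise NonNumericCellError("expression matrix contains non-numeric cells")
        if not np.all(np.isfinite(arr)):
            raise NonNumericCellError("expression matrix contains non-finite values")
        if self.scale == "counts" and (arr < 0).any():
            raise NegativeCountError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA sequence with its auto-derived seed (positions 2–7)."""

    name: str
    species: str         # mouse | human
    mature_seq: str

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise UnknownTokenError(f"unknown species {self.species!r}")
        seq = self.mature_seq.upper().replace("T", "U")
        if set(seq) - RNA_ALPHABET:
            bad = sorted(set(seq) - RNA_ALPHABET)
            raise InvalidAlphabetError(
                f"{self.name}: non-RNA symbols {bad} in mature sequence")
        if len(seq) < 8:
            raise FormatsError(f"{self.name}: mature sequence shorter than 8 nt")
        object.__setattr__(self, "mature_seq", seq)

    @property
    def seed(self) -> str:
        """Seed region: mature positions 2–7, 1-based inclusive."""
        return self.mature_seq[1:7]

    @property
    def base_name(self) -> str:
        """Name with the species prefix (mmu-/hsa-) stripped, lower-cased."""
        name = self.name
        for prefix in ("mmu-", "hsa-"):
            if name.lower().startswith(prefix):
                name = name[len(prefix):]
                break
        return name.lower()


@dataclass
class PredictionTable:
    """Sequence-based miRNA→target predictions from a fixed tool vocabulary."""

    table: pd.DataFrame  # columns: mirna, target, tool
    tools: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"mirna", "target", "tool"}
        if not required <= set(self.table.columns):
            raise FormatsError(f"prediction table needs columns {sorted(required)}")
        if self.table.duplicated(["mirna", "target", "tool"]).any():
            raise DuplicateIdError("duplicate (mirna, target, tool) prediction")
        if not self.tools:
            self.tools = tuple(sorted(self.table["tool"].unique()))
        unknown = set(self.table["tool"]) - set(self.tools)
        if unknown:
            raise UnknownTokenError(f"predictions from unknown tools {sorted(unknown)}")

    def tool_counts(self) -> pd.DataFrame:
        """Distinct-tool support per (mirna, target) pair."""
        counts = (self.table.groupby(["mirna", "target"])["tool"]
                  .nunique().rename("n_tools").reset_index())
        return counts


@dataclass(frozen=True)
class PhenotypeTrajectory:
    """Treated-arm group-mean lung compliance (mL/cmH2O) over the study days."""

    model: str
    days: tuple[int, ...]
    compliance: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise UnknownTokenError(f"unknown model {self.model!r}")
        days = tuple(int(d) for d in self.days)
        comp = tuple(float(c) for c in self.compliance)
        if len(days) != len(comp):
            raise FormatsError("days and compliance must have equal length")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise FormatsError("days must be strictly increasing")
        if any((not np.isfinite(c)) or c <= 0 for c in comp):
            raise FormatsError("compliance values must be finite and > 0")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "compliance", comp)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, kind: str) -> ExpressionMatrix:
    """Read a features × samples count matrix (TSV, or MatrixMarket MTX).

    TSV dialect: tab-separated, UTF-8, header row holds sample ids (first
    header cell ignored), first column holds feature ids.  An MTX file must
    sit next to ``<stem>.features.txt`` and ``<stem>.samples.txt`` sidecars.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such counts file: {path}")
    if path.suffix.lower() == ".mtx":
        values = _read_counts_mtx(path)
    else:
        values = _read_counts_tsv(path)
    return ExpressionMatrix(values=values, kind=kind, scale="counts")


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # malformed structure
        raise FormatsError(f"cannot parse counts TSV {path}: {exc}") from exc
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise NonNumericCellError(f"non-numeric cell in {path}: {exc}") from exc
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns = values.columns.astype(str)
    return values


def _read_counts_mtx(path: Path) -> pd.DataFrame:
    feat_path = path.with_suffix("").with_suffix(".features.txt")
    samp_path = path.with_suffix("").with_suffix(".samples.txt")
    for p in (feat_path, samp_path):
        if not p.exists():
            raise MissingFileError(f"missing MTX sidecar {p}")
    mat = mmread(str(path))
    if hasattr(mat, "todense"):
        mat = mat.todense()
    mat = np.asarray(mat, dtype=float)
    features = feat_path.read_text().split()
    samples = samp_path.read_text().split()
    if mat.shape != (len(features), len(samples)):
        raise FormatsError(
            f"MTX shape {mat.shape} does not match sidecars "
            f"({len(features)} features, {len(samples)} samples)")
    return pd.DataFrame(mat, index=features, columns=samples)


def write_counts(matrix: ExpressionMatrix, path: str | Path,
                 header_comment: str | None = None) -> None:
    """Write a count matrix as TSV (or MTX + sidecars when path ends in .mtx)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mmwrite(str(path), csr_matrix(matrix.values.to_numpy()))
        path.with_suffix("").with_suffix(".features.txt").write_text(
            "\n".join(matrix.feature_ids) + "\n")
        path.with_suffix("").with_suffix(".samples.txt").write_text(
            "\n".join(matrix.sample_ids) + "\n")
        return
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = matrix.values.copy()
        if matrix.scale == "counts" and np.allclose(out.to_numpy() % 1, 0):
            out = out.astype(int)
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path,
                      days: Iterable[int] = DEFAULT_DAYS) -> SampleSheet:
    """Read and validate the study design CSV.

    Required columns: sample_id, model, arm, day, animal_id.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such sample sheet: {path}")
    df = pd.read_csv(path, comment="#", dtype=str)
    required = {"sample_id", "model", "arm", "day", "animal_id"}
    if not required <= set(df.columns):
        raise FormatsError(
            f"sample sheet must have columns {sorted(required)}, got {list(df.columns)}")
    designs = []
    for row in df.itertuples(index=False):
        try:
            day = int(row.day)
        except ValueError as exc:
            raise NonNumericCellError(f"non-integer day {row.day!r}") from exc
        designs.append(SampleDesign(sample_id=str(row.sample_id), model=str(row.model),
                                    arm=str(row.arm), day=day,
                                    animal_id=str(row.animal_id)))
    return SampleSheet(designs, days=days)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# miRNA FASTA
# ---------------------------------------------------------------------------

def read_mirna_fasta(path: str | Path, species: str) -> list[MiRNARecord]:
    """Read mature miRNA records from a miRBase-style FASTA.

    The record name is the first whitespace token of the header; sequences are
    upper-cased and DNA is normalised to RNA (T→U).  Seeds are derived, not read.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such FASTA: {path}")
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise DuplicateIdError(f"duplicate miRNA name {name!r}")
        seen.add(name)
        raw = str(rec.seq).upper()
        if set(raw) - _DNA_OK:
            bad = sorted(set(raw) - _DNA_OK)
            raise InvalidAlphabetError(f"{name}: invalid symbols {bad}")
        records.append(MiRNARecord(name=name, species=species, mature_seq=raw))
    return records


def write_mirna_fasta(records: Sequence[MiRNARecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.mature_seq}\n")


# ---------------------------------------------------------------------------
# Prediction tables, phenotype, contrast tables
# ---------------------------------------------------------------------------

def read_predictions(path: str | Path,
                     tools: Sequence[str] | None = None) -> PredictionTable:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such prediction table: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return PredictionTable(table=df, tools=tuple(tools) if tools else ())


def write_predictions(preds: PredictionTable, path: str | Path,
                      header_comment: str | None = None) -> None:
    _write_tsv(preds.table, path, header_comment)


def read_phenotype(path: str | Path) -> dict[str, PhenotypeTrajectory]:
    """Read per-model compliance trajectories from CSV (model, day, compliance)."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such phenotype file: {path}")
    df = pd.read_csv(path, comment="#")
    out = {}
    for model, grp in df.groupby("model"):
        grp = grp.sort_values("day")
        out[str(model)] = PhenotypeTrajectory(
            model=str(model),
            days=tuple(int(d) for d in grp["day"]),
            compliance=tuple(float(c) for c in grp["compliance"]),
        )
    return out


def write_phenotype(trajectories: Mapping[str, PhenotypeTrajectory],
                    path: str | Path) -> None:
    rows = [(t.model, d, c)
            for t in trajectories.values() for d, c in zip(t.days, t.compliance)]
    pd.DataFrame(rows, columns=["model", "day", "compliance"]).to_csv(path, index=False)


def write_contrasts(contrasts: pd.DataFrame, path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write a contrast table TSV (feature_id, model, day, log2fc, p, adj_p, ...)."""
    _write_tsv(contrasts, path, header_comment)


def read_contrasts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such contrast table: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    df["feature_id"] = df["feature_id"].astype(str)
    if "de_flag" in df.columns:
        df["de_flag"] = df["de_flag"].astype(bool)
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path,
               header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export (Cytoscape SIF / GraphML)
# ---------------------------------------------------------------------------

SIF_RELATIONS = {"mirna_mrna": "represses", "mrna_mrna": "coexpr"}


def write_network(net: nx.DiGraph, path: str | Path, format: str = "sif") -> None:
    """Export a regulatory network for Cytoscape.

    SIF rows are ``source <relation> target`` with relation ``represses`` for
    miRNA→mRNA edges and ``coexpr`` for mRNA–mRNA co-expression edges.  GraphML
    carries every node and edge annotation as an attribute.
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in net.edges(data=True):
                rel = SIF_RELATIONS.get(data.get("kind", ""), data.get("kind", "edge"))
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif format == "graphml":
        clean = nx.DiGraph(**{k: v for k, v in net.graph.items()})
        for n, data in net.nodes(data=True):
            clean.add_node(n, **{k: _graphml_safe(v) for k, v in data.items()})
        for u, v, data in net.edges(data=True):
            clean.add_edge(u, v, **{k: _graphml_safe(val) for k, val in data.items()})
        nx.write_graphml(clean, str(path))
    else:
        raise UnknownTokenError(f"unknown network format {format!r}")


def _graphml_safe(value):
    # GraphML attributes must be scalar; NaN floats survive as floats
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def read_network_graphml(path: str | Path) -> nx.DiGraph:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such network file: {path}")
    return nx.read_graphml(str(path))
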