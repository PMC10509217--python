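"""Plain-text I/O for connectomes, atlas partitions and cohort tables.

Connectomes are square, symmetric, zero-diagonal, non-negative weighted
adjacency matrices stored as whitespace- or comma-delimited text (optionally
gzipped), with an optional header row of node identifiers.  Atlas and cohort
tables are TSV/CSV with a header.  Node order is the contract throughout:
an atlas and a connectome paired in an analysis must share identical ordered
node identifiers; no name-based reindexing is ever performed.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: The eight canonical functional networks nodes may belong to.
CANONICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
    "subcortical",
)

#: Default edge-weight threshold: weights strictly below are zeroed.
DEFAULT_THRESHOLD = 0.001

_GROUPS = ("term", "preterm")
_SCANS = ("birth", "TEA")
#: Admissible (group, scan) combinations: term infants are scanned once at
#: term-equivalent-era age, preterm infants at birth and again at TEA.
_ALLOWED_GROUP_SCAN = {("term", "TEA"), ("preterm", "birth"), ("preterm", "TEA")}


# ---------------------------------------------------------------------------
# Connectome


@dataclass(frozen=True)
class Connectome:
    """A weighted, undirected structural brain network.

    Attributes
    ----------
    node_ids : tuple of str
        Ordered node identifiers; the i-th id labels row/column i of ``A``.
    A : ndarray of shape (n, n)
        Symmetric, zero-diagonal, non-negative edge weights on a
        dimensionless 0-1 (quantitative-anisotropy-like) scale.
    """

    node_ids: tuple
    A: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def strengths(self) -> np.ndarray:
        """Per-node strength (weighted degree)."""
        return self.A.sum(axis=1)

    def density(self) -> float:
        """Fraction of possible undirected edges with nonzero weight."""
        n = self.n_nodes
        if n < 2:
            return 0.0
        return float(np.count_nonzero(np.triu(self.A, 1)) / (n * (n - 1) / 2))


def validate_connectome(
    node_ids: Sequence[str],
    A: np.ndarray,
    tol: float = 1e-8,
) -> Connectome:
    """Validate an adjacency matrix and wrap it as a :class:`Connectome`.

    Raises
    ------
    FormatError
        If ``A`` is not square or does not match ``node_ids`` in length.
    ValidationError
        On NaN/Inf entries, asymmetry beyond ``tol``, negative weights, or a
        nonzero diagonal.  Asymmetric input is an error, never silently
        symmetrized; see :func:`symmetrize` for the explicit repair.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise FormatError(f"adjacency matrix must be square, got shape {A.shape}")
    if len(node_ids) != A.shape[0]:
        raise FormatError(
            f"{len(node_ids)} node ids for a {A.shape[0]}x{A.shape[1]} matrix"
        )
    if len(set(node_ids)) != len(node_ids):
        raise ValidationError("duplicate node ids")
    if not np.all(np.isfinite(A)):
        raise ValidationError("adjacency matrix contains NaN or Inf entries")
    asym = np.max(np.abs(A - A.T)) if A.size else 0.0
    if asym > tol:
        raise ValidationError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}; "
            "use nnct.io.symmetrize explicitly if this is intended"
        )
    if np.any(A < 0):
        raise ValidationError("negative edge weights")
    if A.size and np.max(np.abs(np.diag(A))) > 0:
        raise ValidationError("diagonal entries must be zero")
    return Connectome(node_ids=tuple(node_ids), A=A)


def apply_threshold(A: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Zero out weights strictly below ``threshold`` (idempotent)."""
    A = np.array(A, dtype=float, copy=True)
    A[A < threshold] = 0.0
    return A


def symmetrize(A: np.ndarray) -> np.ndarray:
    """Explicit symmetrization: the elementwise mean of ``A`` and its
    transpose.  Provided as a separate utility so that asymmetric input to
    :func:`read_connectome` stays a hard error by default."""
    A = np.asarray(A, dtype=float)
    return (A + A.T) / 2.0


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_connectome(
    path,
    tol: float = 1e-8,
    threshold: float = DEFAULT_THRESHOLD,
) -> Connectome:
    """Read a connectome from a delimited square matrix file.

    The file may start with a header row of node identifiers; otherwise nodes
    are named ``n001 .. nNNN``.  Both whitespace and comma delimiters are
    accepted, and ``.gz`` files are decompressed transparently.  Weights
    strictly below ``threshold`` are zeroed, the diagonal is forced to zero,
    and the result is validated (symmetry within ``tol``, non-negativity).
    """
    with _open_text(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")

    def tokens(line):
        return line.replace(",", " ").split()

    first = tokens(lines[0])
    try:
        [float(t) for t in first]
        header = None
        body = lines
    except ValueError:
        header = first
        body = lines[1:]

    rows = []
    for ln in body:
        try:
            rows.append([float(t) for t in tokens(ln)])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric entry in matrix body: {exc}")
    if not rows:
        raise FormatError(f"{path}: header but no matrix body")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows with widths {sorted(widths)}")
    A = np.array(rows, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise FormatError(f"{path}: matrix is {A.shape[0]}x{A.shape[1]}, not square")
    if header is not None and len(header) != A.shape[0]:
        raise FormatError(
            f"{path}: header names {len(header)} nodes for a {A.shape[0]}-row matrix"
        )
    node_ids = header if header is not None else [f"n{i+1:03d}" for i in range(A.shape[0])]
    # validate symmetry/negativity on the raw matrix first, then clean
    probe = A.copy()
    np.fill_diagonal(probe, 0.0)
    validate_connectome(node_ids, probe, tol=tol)
    A = apply_threshold(probe, threshold)
    A = (A + A.T) / 2.0  # remove sub-tol asymmetry left by the file
    return Connectome(node_ids=tuple(node_ids), A=A)


def write_connectome(C: Connectome, path, header: bool = True, fmt: str = "%.10g") -> None:
    """Write a connectome as tab-delimited text (``.gz`` compresses)."""
    path = Path(path)
    buf = _io.StringIO()
    if header:
        buf.write("\t".join(C.node_ids) + "\n")
    for row in C.A:
        buf.write("\t".join(fmt % v for v in row) + "\n")
    data = buf.getvalue()
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(data)
    else:
        path.write_text(data)


# ---------------------------------------------------------------------------
# Atlas


@dataclass(frozen=True)
class Atlas:
    """Node -> (label, lobe, functional network) partition for an ordered
    node set.  Network labels are restricted to :data:`CANONICAL_NETWORKS`."""

    node_ids: tuple
    labels: tuple
    lobes: tuple
    networks: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def network_members(self, network: str) -> np.ndarray:
        """Boolean membership mask for one functional network."""
        if network not in CANONICAL_NETWORKS:
            raise ValidationError(f"unknown network {network!r}")
        return np.array([nw == network for nw in self.networks])

    def networks_present(self) -> tuple:
        """Canonical networks with at least one member node, in canonical order."""
        present = set(self.networks)
        return tuple(nw for nw in CANONICAL_NETWORKS if nw in present)


def read_atlas(path) -> Atlas:
    """Read an atlas table (TSV/CSV with columns node_id, label, lobe,
    network) and validate its network vocabulary."""
    df = _read_table(path, required=("node_id", "label", "lobe", "network"))
    ids = df["node_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = df["node_id"][df["node_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate node_id in atlas: {dupes}")
    bad = sorted(set(df["network"]) - set(CANONICAL_NETWORKS))
    if bad:
        raise ValidationError(
            f"unknown network label(s) {bad}; expected one of {CANONICAL_NETWORKS}"
        )
    return Atlas(
        node_ids=tuple(ids),
        labels=tuple(df["label"].astype(str)),
        lobes=tuple(df["lobe"].astype(str)),
        networks=tuple(df["network"].astype(str)),
    )


def write_atlas(atlas: Atlas, path) -> None:
    pd.DataFrame(
        {
            "node_id": atlas.node_ids,
            "label": atlas.labels,
            "lobe": atlas.lobes,
            "network": atlas.networks,
        }
    ).to_csv(path, sep="\t", index=False)


def check_atlas_matches(C: Connectome, atlas: Atlas) -> None:
    """Enforce the node-order contract between a connectome and an atlas."""
    if tuple(C.node_ids) != tuple(atlas.node_ids):
        raise ValidationError("connectome and atlas node ids differ in content or order")


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class SubjectRecord:
    """One (subject, scan) row of a cohort table."""

    subject_id: str
    group: str  # "term" | "preterm"
    scan: str  # "birth" | "TEA"
    ga_weeks: float
    pma_weeks: float
    sex: str
    brain_volume: float
    motion_translation: float
    motion_rotation: float
    outlier_ratio: float
    bsid_cognition: float | None = None
    bsid_language: float | None = None
    bsid_motor: float | None = None
    connectome_path: str | None = None

    def validate(self) -> "SubjectRecord":
        if self.group not in _GROUPS:
            raise ValidationError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.scan not in _SCANS:
            raise ValidationError(f"{self.subject_id}: unknown scan {self.scan!r}")
        if (self.group, self.scan) not in _ALLOWED_GROUP_SCAN:
            raise ValidationError(
                f"{self.subject_id}: disallowed group/scan combination "
                f"({self.group}, {self.scan})"
            )
        if self.pma_weeks < self.ga_weeks:
            raise ValidationError(
                f"{self.subject_id}: PMA at scan ({self.pma_weeks}) earlier than "
                f"GA at birth ({self.ga_weeks})"
            )
        return self


@dataclass
class Cohort:
    """An ordered list of subject records with grouping helpers."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        keys = [(r.subject_id, r.scan) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (subject, scan) rows: {dupes}")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def by_group(self, group: str, scan: str | None = None) -> list:
        return [
            r
            for r in self.records
            if r.group == group and (scan is None or r.scan == scan)
        ]

    def by_scan(self, scan: str) -> list:
        return [r for r in self.records if r.scan == scan]

    def longitudinal_pairs(self) -> list:
        """(birth record, TEA record) pairs for subjects scanned twice."""
        birth = {r.subject_id: r for r in self.records if r.scan == "birth"}
        tea = {r.subject_id: r for r in self.records if r.scan == "TEA"}
        return [(birth[s], tea[s]) for s in birth if s in tea]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


_COHORT_REQUIRED = (
    "subject_id",
    "group",
    "scan",
    "ga_weeks",
    "pma_weeks",
    "sex",
    "brain_volume",
    "motion_translation",
    "motion_rotation",
    "outlier_ratio",
)
_COHORT_OPTIONAL = ("bsid_cognition", "bsid_language", "bsid_motor", "connectome_path")


def read_cohort(path) -> Cohort:
    """Read a cohort table (one row per subject x scan) with type checking."""
    df = _read_table(path, required=_COHORT_REQUIRED)
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _COHORT_REQUIRED}
        for c in _COHORT_OPTIONAL:
            if c in df.columns and not pd.isna(row[c]):
                kwargs[c] = row[c]
        kwargs["subject_id"] = str(kwargs["subject_id"])
        kwargs["group"] = str(kwargs["group"])
        kwargs["scan"] = str(kwargs["scan"])
        kwargs["sex"] = str(kwargs["sex"])
        for c in ("ga_weeks", "pma_weeks", "brain_volume", "motion_translation",
                  "motion_rotation", "outlier_ratio"):
            try:
                kwargs[c] = float(kwargs[c])
            except (TypeError, ValueError):
                raise FormatError(f"non-numeric value {row[c]!r} in column {c}")
        records.append(SubjectRecord(**kwargs))
    return Cohort(records=records)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


def _read_table(path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.name.endswith((".csv", ".csv.gz")) else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df
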