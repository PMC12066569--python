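"""Benchmark-style matrix files and k-nearest-neighbour similarity graphs.

A dataset directory holds three delimited matrix files with identifier
headers: ``drug_sim.tsv`` (drug-drug similarity), ``disease_sim.tsv``
(disease-disease similarity) and ``associations.tsv`` (binary drug x disease
association matrix).  Similarity matrices are square, symmetric, unit
diagonal, entries in [0, 1].  The KNN graph connects every entity to its k
most similar peers (ties broken by lowest index), is symmetrised by union,
and carries a self-loop on every node so each node belongs to its own
neighbourhood.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "AssociationMatrix",
    "KnnGraph",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix_file",
    "write_matrix_file",
    "build_knn_adjacency",
    "load_dataset_dir",
    "DatasetBundle",
    "BENCHMARK_STATS",
    "check_benchmark_stats",
]

SYMMETRY_TOL = 1e-8


class MatrixParseError(ValueError):
    """Malformed matrix file (header, delimiter, or non-numeric cell)."""


class MatrixValidationError(ValueError):
    """A parsed matrix violates a domain invariant."""


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity scores in [0, 1] with unit diagonal."""

    entity_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise MatrixValidationError(
                f"similarity matrix is {self.values.shape}, expected ({n}, {n})"
            )
        asym = np.abs(self.values - self.values.T)
        if asym.max(initial=0.0) > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise MatrixValidationError(
                f"similarity asymmetry {asym[i, j]:.3e} at cell "
                f"({self.entity_ids[i]}, {self.entity_ids[j]}) exceeds "
                f"{SYMMETRY_TOL}"
            )
        if not np.allclose(np.diag(self.values), 1.0):
            raise MatrixValidationError("similarity diagonal must equal 1")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise MatrixValidationError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.entity_ids)


@dataclass
class AssociationMatrix:
    """Binary drugs x diseases matrix of known associations."""

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.drug_ids), len(self.disease_ids))
        if self.values.shape != shape:
            raise MatrixValidationError(
                f"association matrix is {self.values.shape}, expected {shape}"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            bad = self.values[~np.isin(self.values, (0.0, 1.0))][0]
            raise MatrixValidationError(
                f"association entries must be 0 or 1, found {bad}"
            )
        if self.values.sum() < 1:
            raise MatrixValidationError("association matrix has no positives")
        self.values = self.values.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


@dataclass
class KnnGraph:
    """Binary adjacency (symmetric, self-loops) plus node features."""

    adjacency: np.ndarray
    features: np.ndarray
    k: int

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        if not (self.adjacency == self.adjacency.T).all():
            raise MatrixValidationError("KNN adjacency must be symmetric")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise MatrixValidationError("KNN adjacency must be binary")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def _read_frame(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0,
                         float_precision="round_trip")
    except Exception as exc:  # malformed delimiter/structure
        raise MatrixParseError(f"{path}: cannot parse matrix file: {exc}") from exc
    if df.shape[1] == 0:
        raise MatrixParseError(f"{path}: no data columns found")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MatrixParseError(f"{path}: non-numeric cell: {exc}") from exc
    if np.isnan(values).any():
        raise MatrixParseError(f"{path}: missing or non-numeric cell")
    return df


def read_matrix_file(path: str, kind: str):
    """Read a delimited matrix with id headers.

    kind='similarity' returns a SimilarityMatrix, kind='association' an
    AssociationMatrix.  Invariant violations raise rather than being
    silently repaired.
    """
    df = _read_frame(path)
    values = df.to_numpy(dtype=float)
    if kind == "similarity":
        return SimilarityMatrix([str(i) for i in df.index], values)
    if kind == "association":
        return AssociationMatrix(
            [str(i) for i in df.index], [str(c) for c in df.columns], values
        )
    raise ValueError(f"unknown kind {kind!r}")


def write_matrix_file(matrix, path: str) -> None:
    """Write a SimilarityMatrix or AssociationMatrix as TSV (round-trips)."""
    if isinstance(matrix, SimilarityMatrix):
        df = pd.DataFrame(
            matrix.values, index=matrix.entity_ids, columns=matrix.entity_ids
        )
    elif isinstance(matrix, AssociationMatrix):
        df = pd.DataFrame(
            matrix.values.astype(int),
            index=matrix.drug_ids,
            columns=matrix.disease_ids,
        )
    else:
        raise TypeError(type(matrix))
    df.to_csv(path, sep="\t", float_format="%.17g")


def build_knn_adjacency(sim: SimilarityMatrix, k: int) -> KnnGraph:
    """KNN graph of a similarity matrix.

    Each node picks its k most similar *other* nodes (stable descending
    sort, so similarity ties go to the lowest index); the directed edge set
    is symmetrised by union and self-loops are added.  Node features default
    to the rows of the similarity matrix itself.
    """
    n = sim.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        order = np.argsort(-sim.values[i], kind="stable")
        picks = [j for j in order if j != i][:k]
        adj[i, picks] = 1
    adj = np.maximum(adj, adj.T)  # union symmetrisation
    np.fill_diagonal(adj, 1)
    return KnnGraph(adjacency=adj, features=sim.values.copy(), k=k)


@dataclass
class DatasetBundle:
    """Everything one run needs: two similarity views plus associations."""

    drug_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    associations: AssociationMatrix
    latent: dict = field(default_factory=dict)  # ground truth, synthetic only

    def __post_init__(self):
        if self.drug_sim.entity_ids != self.associations.drug_ids:
            raise MatrixValidationError("drug id mismatch between files")
        if self.disease_sim.entity_ids != self.associations.disease_ids:
            raise MatrixValidationError("disease id mismatch between files")


FILE_NAMES = {
    "drug_sim": "drug_sim.tsv",
    "disease_sim": "disease_sim.tsv",
    "associations": "associations.tsv",
}


def load_dataset_dir(path: str) -> DatasetBundle:
    """Load the three-file dataset directory convention."""
    return DatasetBundle(
        drug_sim=read_matrix_file(
            os.path.join(path, FILE_NAMES["drug_sim"]), "similarity"
        ),
        disease_sim=read_matrix_file(
            os.path.join(path, FILE_NAMES["disease_sim"]), "similarity"
        ),
        associations=read_matrix_file(
            os.path.join(path, FILE_NAMES["associations"]), "association"
        ),
    )


# Published statistics of the three standard drug-repositioning benchmarks:
# (n_drugs, n_diseases, n_known_associations).
BENCHMARK_STATS = {
    "Fdataset": (468, 298, 1632),
    "Cdataset": (663, 409, 2352),
    "LRSSL": (763, 681, 3051),
}


def check_benchmark_stats(bundle: DatasetBundle, name: str) -> None:
    """Verify a user-supplied benchmark against its published statistics."""
    n_drugs, n_diseases, n_assoc = BENCHMARK_STATS[name]
    got = (
        bundle.associations.n_drugs,
        bundle.associations.n_diseases,
        int(bundle.associations.values.sum()),
    )
    if got != (n_drugs, n_diseases, n_assoc):
        raise MatrixValidationError(
            f"{name}: expected {n_drugs} drugs x {n_diseases} diseases with "
            f"{n_assoc} associations, found {got[0]} x {got[1]} with {got[2]}"
        )
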