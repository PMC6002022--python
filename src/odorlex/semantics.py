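"""Descriptor-descriptor dissimilarities and low-dimensional maps.

Two notions of descriptor similarity are compared throughout the package:

* *correlation*: one minus the Pearson correlation between two descriptors'
  binary catalog columns.  In exclusively-annotated catalogs this measure
  collapses -- semantically close descriptors are almost never applied to
  the same chemical, so their correlation vanishes;
* *cosine*: one minus the cosine similarity between the descriptors'
  pre-trained word-embedding vectors, which recovers the semantic
  neighbourhoods the catalog hides.

Classical (metric) MDS projects either dissimilarity matrix to 2-D for
visual inspection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalog import SensoryCatalog

logger = logging.getLogger(__name__)


class SemanticsError(ValueError):
    """Raised for invalid embeddings or dissimilarity inputs."""


@dataclass
class EmbeddingTable:
    """Word -> dense vector lookup table (word2vec-style).

    The skip-gram training that produces such vectors is upstream of this
    package; vectors are consumed read-only.  ``metadata`` records the
    provenance hyperparameters (hidden units, window size, minimum count)
    when known.
    """

    vectors: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vectors:
            raise SemanticsError("embedding table is empty")
        dims = {len(v) for v in self.vectors.values()}
        if len(dims) != 1:
            raise SemanticsError(f"inconsistent vector lengths: {sorted(dims)}")
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in self.vectors.items()}

    @property
    def dim(self) -> int:
        return len(next(iter(self.vectors.values())))

    @property
    def vocabulary(self) -> set[str]:
        return set(self.vectors)

    def resolve(self, word: str) -> np.ndarray:
        """Look up a descriptor, with a compound-word fallback.

        Exact lowercase match first; otherwise hyphen/space-separated
        tokens ("tutti frutti") are looked up individually and averaged.
        Unresolvable words raise.
        """
        key = word.strip().lower()
        if key in self.vectors:
            return self.vectors[key]
        tokens = key.replace("-", " ").split()
        if len(tokens) > 1 and all(t in self.vectors for t in tokens):
            return np.mean([self.vectors[t] for t in tokens], axis=0)
        raise SemanticsError(f"descriptor not in embedding vocabulary: {word!r}")


def read_word_vectors(path, *, metadata: dict | None = None) -> EmbeddingTable:
    """Read word2vec text format: header "vocab_size dim", then word + floats."""
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise SemanticsError("expected 'vocab_size dim' header line")
        n_words, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                raise SemanticsError(f"line {lineno}: expected {dim} components")
            vectors[parts[0]] = np.array(parts[1 : dim + 1], dtype=float)
    if len(vectors) != n_words:
        logger.warning(
            "word-vector header declared %d words, found %d", n_words, len(vectors)
        )
    return EmbeddingTable(vectors, metadata=metadata or {})


def write_word_vectors(emb: EmbeddingTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(emb.vectors)} {emb.dim}\n")
        for word, vec in emb.vectors.items():
            fh.write(word + " " + " ".join(repr(float(x)) for x in vec) + "\n")


@dataclass
class DistanceMatrix:
    """Symmetric descriptor-descriptor dissimilarity matrix.

    ``method`` tags the construction ("correlation" or "cosine"); both
    produce values in [0, 2] with a zero diagonal.
    """

    labels: list[str]
    values: np.ndarray = field(repr=False)
    method: str = "cosine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise SemanticsError(f"distance matrix shape {self.values.shape} != ({n},{n})")
        if np.isnan(self.values).any():
            raise SemanticsError("distance matrix contains NaN")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise SemanticsError("distance matrix is not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise SemanticsError("distance matrix diagonal is not zero")
        if self.values.min(initial=0.0) < -1e-12:
            raise SemanticsError("negative dissimilarity")
        # exact symmetry/zero-diagonal for downstream determinism
        self.values = np.maximum((self.values + self.values.T) / 2.0, 0.0)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)


def correlation_dissimilarity(cat: SensoryCatalog) -> DistanceMatrix:
    """d(i, j) = 1 - Pearson r of binary catalog columns i and j.

    Zero-variance columns have undefined correlations; their r against any
    other column is taken as 0 (dissimilarity 1) with a warning, keeping
    the matrix total.
    """
    if cat.n_chemicals < 2:
        raise SemanticsError("need >= 2 chemicals for column correlations")
    x = cat.matrix.astype(float)
    centered = x - x.mean(axis=0)
    sd = centered.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance descriptor column(s); correlations set to 0",
            int(degenerate.sum()),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    z = centered / safe_sd
    r = (z.T @ z) / x.shape[0]
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return DistanceMatrix(list(cat.descriptor_names), 1.0 - r, method="correlation")


def cosine_dissimilarity(descriptors: list[str], emb: EmbeddingTable) -> DistanceMatrix:
    """d(i, j) = 1 - cos(v_i, v_j) over the descriptors' embedding vectors."""
    missing = []
    vecs = []
    for d in descriptors:
        try:
            vecs.append(emb.resolve(d))
        except SemanticsError:
            missing.append(d)
    if missing:
        raise SemanticsError(f"descriptors not resolvable in embedding: {missing}")
    V = np.array(vecs)
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        zero = [d for d, nn in zip(descriptors, norms) if nn == 0]
        raise SemanticsError(f"zero embedding vector(s) for: {zero}")
    unit = V / norms[:, None]
    d = 1.0 - np.clip(unit @ unit.T, -1.0, 1.0)
    return DistanceMatrix(list(descriptors), d, method="cosine")


def mds_embed(dm: DistanceMatrix, out_dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS.

    Double-centers the squared-distance matrix, eigendecomposes, and
    returns the top ``out_dim`` coordinate columns (centered at the
    origin).  Negative eigenvalues -- non-Euclidean structure -- are
    truncated at zero; if fewer than ``out_dim`` positive eigenvalues
    exist the remaining columns are zero, with a warning.
    """
    if out_dim < 1:
        raise SemanticsError("out_dim must be >= 1")
    n = dm.n
    D2 = dm.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > 1e-12).sum())
    if n_pos < out_dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); padding MDS output with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, out_dim))
    k = min(out_dim, n_pos)
    if k:
        coords[:, :k] = eigvec[:, :k] * np.sqrt(eigval[:k])
    return coords
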