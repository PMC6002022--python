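"""Binary sensory catalogs: chemicals x descriptors presence/absence tables.

Vendor odor catalogs record, for each chemical, which verbal descriptors
("rose", "balsamic", ...) apply.  The table is strictly binary -- no graded
applicability -- and extremely sparse, which is what makes the downstream
descriptor-clustering step necessary in the first place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class CatalogError(ValueError):
    """Raised for malformed or invalid sensory-catalog input."""


@dataclass
class SensoryCatalog:
    """Chemicals x descriptors binary applicability matrix.

    Parameters
    ----------
    chemical_ids : list of str
        Unique identifiers, one per row.
    descriptor_names : list of str
        Unique lowercase descriptor names, one per column.
    matrix : ndarray of shape (n_chemicals, n_descriptors)
        Entries in {0, 1}, dtype int8.
    """

    chemical_ids: list[str]
    descriptor_names: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise CatalogError("catalog matrix must be 2-D")
        if self.matrix.shape != (len(self.chemical_ids), len(self.descriptor_names)):
            raise CatalogError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.chemical_ids)} chemicals x "
                f"{len(self.descriptor_names)} descriptors"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise CatalogError("catalog entries must all be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)
        if len(set(self.chemical_ids)) != len(self.chemical_ids):
            raise CatalogError("duplicate chemical ids")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise CatalogError("duplicate descriptor names")

    @property
    def n_chemicals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.matrix.shape[1]

    def descriptor_counts(self) -> np.ndarray:
        """Occurrence count (column sum) of each descriptor."""
        return self.matrix.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensoryCatalog):
            return NotImplemented
        return (
            self.chemical_ids == other.chemical_ids
            and self.descriptor_names == other.descriptor_names
            and np.array_equal(self.matrix, other.matrix)
        )


def _normalize_name(name: str) -> str:
    # descriptors must later key into an embedding vocabulary, so canonicalize
    return str(name).strip().lower()


def read_catalog(path, *, dialect: str = "csv") -> SensoryCatalog:
    """Read a sensory catalog from CSV.

    Layout: first column = chemical id, header row = descriptor names,
    cells strictly 0/1.  Descriptor names are lowercased and stripped on
    ingest.  Logs a one-line summary (sizes + sparsity) per read.

    Raises
    ------
    CatalogError
        On a non-binary cell (named by row/column) or duplicate names.
    """
    if dialect != "csv":
        raise CatalogError(f"unknown catalog dialect: {dialect!r}")
    df = pd.read_csv(path, index_col=0)
    descriptor_names = [_normalize_name(c) for c in df.columns]
    chemical_ids = [str(i) for i in df.index]

    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    bad = ~np.isin(numeric, (0.0, 1.0)) | np.isnan(numeric)
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        i, j = divmod(flat, df.shape[1])
        raise CatalogError(
            f"non-binary cell {values[i, j]!r} at chemical "
            f"{chemical_ids[i]!r}, descriptor {descriptor_names[j]!r}"
        )
    matrix = numeric.reshape(df.shape).astype(np.int8)

    cat = SensoryCatalog(chemical_ids, descriptor_names, matrix)
    empty_rows = int((matrix.sum(axis=1) == 0).sum())
    if empty_rows:
        logger.warning("%d chemical(s) have an all-zero descriptor row", empty_rows)
    logger.info(
        "read catalog: %d chemicals x %d descriptors, sparsity %.4f",
        cat.n_chemicals, cat.n_descriptors, sparsity(cat),
    )
    return cat


def write_catalog(cat: SensoryCatalog, path) -> None:
    """Write a catalog in the layout :func:`read_catalog` consumes."""
    df = pd.DataFrame(cat.matrix, index=cat.chemical_ids, columns=cat.descriptor_names)
    df.index.name = "chemical_id"
    df.to_csv(path)


def filter_rare_descriptors(
    cat: SensoryCatalog, min_count: int = 4
) -> tuple[SensoryCatalog, list[str]]:
    """Drop descriptors used fewer than ``min_count`` times.

    A descriptor is removed iff its occurrence count is < ``min_count``;
    with the default ``min_count=4`` this removes descriptors appearing
    three times or less.  Chemicals are never dropped.

    Returns the filtered catalog and the removed descriptor names.
    """
    if min_count < 1:
        raise CatalogError("min_count must be >= 1")
    counts = cat.descriptor_counts()
    keep = counts >= min_count
    if not keep.any():
        raise CatalogError("rarity filter would remove every descriptor")
    removed = [d for d, k in zip(cat.descriptor_names, keep) if not k]
    kept_names = [d for d, k in zip(cat.descriptor_names, keep) if k]
    filtered = SensoryCatalog(
        list(cat.chemical_ids), kept_names, cat.matrix[:, keep]
    )
    if removed:
        logger.info("rarity filter removed %d descriptor(s)", len(removed))
    return filtered, removed


def sparsity(cat: SensoryCatalog) -> float:
    """Fraction of zero entries, in [0, 1]."""
    if cat.matrix.size == 0:
        raise CatalogError("sparsity undefined for an empty catalog")
    return float(1.0 - cat.matrix.mean())
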