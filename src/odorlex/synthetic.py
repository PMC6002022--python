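"""Seeded synthetic worlds with the statistical structure the method assumes.

A world bundles four linked pieces: a sparse binary sensory catalog, EI-style
mass spectra, descriptor word embeddings, and the planted group truth.  Each
chemical belongs to 1-3 latent odor groups.  The catalog's ``exclusive`` mode
reproduces the annotation habit that motivates the whole pipeline: within an
active group exactly ONE member descriptor is marked, chosen at random, so
two semantically near-identical descriptors almost never co-occur and their
column correlation vanishes.  Non-exclusive mode marks every member with
probability 0.8, the regime of graded sensory panels where within-group
correlations are high.  Embeddings place each group on its own direction so
cosine distances still see the semantic structure the catalog hides; spectra
mix nonnegative group basis patterns so the labels are learnable from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import SensoryCatalog
from .clustering import ClusterAssignment
from .semantics import EmbeddingTable
from .spectra import RawSpectrum

#: real odor vocabulary, grouped by impression, used for descriptor names
GROUP_WORDS = [
    ["rose", "lily", "violet", "jasmine", "iris", "lavender"],
    ["milk", "cheese", "butter", "cream", "yogurt", "dairy"],
    ["apple", "banana", "cherry", "peach", "lemon", "orange"],
    ["clove", "cinnamon", "pepper", "nutmeg", "ginger", "anise"],
    ["cedar", "pine", "sandalwood", "oak", "resin", "balsam"],
    ["grass", "leaf", "mint", "cucumber", "herb", "hay"],
    ["almond", "hazelnut", "walnut", "peanut", "roasted", "malt"],
    ["smoke", "tar", "leather", "musk", "amber", "earthy"],
]

#: names for injected rare descriptors; the last is deliberately absent from
#: generated embedding tables to exercise the out-of-vocabulary error path
RARE_WORDS = ["ozone", "metallic", "waxy", "camphor", "petrichor"]

#: m/z of the first synthetic spectrum bin (inside the default window)
SYNTH_MZ_LO = 51


class SyntheticError(ValueError):
    """Raised for infeasible synthetic-world configurations."""


@dataclass
class SyntheticConfig:
    """Knobs of the generated world; defaults are the study conditions.

    group_separation scales the distance between group mean directions in
    embedding space relative to the fixed member noise (sd 0.05); values
    above ~0.5 make the planted partition recoverable by UPGMA on cosine
    distances.
    """

    n_chemicals: int = 180
    n_groups: int = 6
    descriptors_per_group: int = 5
    exclusive: bool = True
    embed_dim: int = 16
    group_separation: float = 1.0
    spectrum_dim: int = 64
    latent_rank: int | None = None
    noise_sd: float = 0.02
    rare_descriptor_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1 or self.n_groups < 1 or self.descriptors_per_group < 1:
            raise SyntheticError("counts must be >= 1")
        if self.noise_sd < 0 or self.group_separation <= 0:
            raise SyntheticError("noise_sd >= 0 and group_separation > 0 required")
        if self.n_groups > len(GROUP_WORDS):
            raise SyntheticError(f"at most {len(GROUP_WORDS)} groups supported")
        if self.descriptors_per_group > len(GROUP_WORDS[0]):
            raise SyntheticError(
                f"at most {len(GROUP_WORDS[0])} descriptors per group supported"
            )
        if self.embed_dim < self.n_groups:
            raise SyntheticError("embed_dim must be >= n_groups")
        if self.rare_descriptor_count > len(RARE_WORDS):
            raise SyntheticError(f"at most {len(RARE_WORDS)} rare descriptors")


def generate_world(
    cfg: SyntheticConfig,
) -> tuple[SensoryCatalog, list[RawSpectrum], EmbeddingTable, ClusterAssignment]:
    """Generate (catalog, spectra, embeddings, true group assignment).

    Same config (including seed) gives a byte-identical world.  Injected
    rare descriptors occur at most 3 times each, so the default rarity
    filter removes exactly them; they carry no embedding entry for the
    final name in :data:`RARE_WORDS`, exercising the OOV error path when
    filtering is skipped.
    """
    rng = np.random.default_rng(cfg.seed)
    G, dpg = cfg.n_groups, cfg.descriptors_per_group
    latent_rank = cfg.latent_rank if cfg.latent_rank is not None else G

    descriptors = [w for g in range(G) for w in GROUP_WORDS[g][:dpg]]
    true_groups = ClusterAssignment(
        G, {w: g for g in range(G) for w in GROUP_WORDS[g][:dpg]}
    )

    # chemical -> 1..3 active latent groups (without replacement)
    membership = np.zeros((cfg.n_chemicals, G), dtype=np.int8)
    for i in range(cfg.n_chemicals):
        n_active = int(rng.integers(1, min(3, G) + 1))
        membership[i, rng.choice(G, size=n_active, replace=False)] = 1

    # catalog: exclusive -> one member per active group; else each w.p. 0.8
    cat_matrix = np.zeros((cfg.n_chemicals, len(descriptors)), dtype=np.int8)
    for i in range(cfg.n_chemicals):
        for g in np.flatnonzero(membership[i]):
            if cfg.exclusive:
                j = int(rng.integers(dpg))
                cat_matrix[i, g * dpg + j] = 1
            else:
                hits = rng.random(dpg) < 0.8
                cat_matrix[i, g * dpg : (g + 1) * dpg] = hits.astype(np.int8)

    # rare descriptor columns (each used 1..3 times) to exercise the filter
    rare_names = RARE_WORDS[-cfg.rare_descriptor_count:] if cfg.rare_descriptor_count else []
    if rare_names:
        rare_cols = np.zeros((cfg.n_chemicals, len(rare_names)), dtype=np.int8)
        for j in range(len(rare_names)):
            hits = rng.choice(cfg.n_chemicals, size=int(rng.integers(1, 4)), replace=False)
            rare_cols[hits, j] = 1
        cat_matrix = np.hstack([cat_matrix, rare_cols])
    catalog = SensoryCatalog(
        [f"chem{i:04d}" for i in range(cfg.n_chemicals)],
        descriptors + rare_names,
        cat_matrix,
    )

    # embeddings: orthonormal group directions scaled by group_separation,
    # members perturbed by small isotropic noise
    basis, _ = np.linalg.qr(rng.normal(size=(cfg.embed_dim, G)))
    member_noise = 0.05
    vectors: dict[str, np.ndarray] = {}
    for g in range(G):
        mean = cfg.group_separation * basis[:, g]
        for w in GROUP_WORDS[g][:dpg]:
            vectors[w] = mean + rng.normal(0.0, member_noise, cfg.embed_dim)
    for name in rare_names[:-1] if rare_names else []:
        vectors[name] = rng.normal(0.0, 1.0, cfg.embed_dim)
    # rare_names[-1] (if any) is intentionally left out of the vocabulary
    emb = EmbeddingTable(vectors, metadata={"source": "synthetic", "seed": cfg.seed})

    # spectra: nonnegative latent basis patterns mixed per chemical
    B = rng.random((latent_rank, cfg.spectrum_dim)) ** 2
    if latent_rank == G:
        loadings = np.eye(G)
    else:
        loadings = rng.random((G, latent_rank))
    spectra: list[RawSpectrum] = []
    for i in range(cfg.n_chemicals):
        weights = membership[i].astype(float) * rng.uniform(0.5, 1.5, G)
        signal = (weights @ loadings) @ B
        if cfg.noise_sd > 0:
            signal = signal + rng.normal(0.0, cfg.noise_sd, cfg.spectrum_dim)
        signal = np.clip(signal, 0.0, None)
        peaks = {SYNTH_MZ_LO + j: float(v) for j, v in enumerate(signal) if v > 0}
        spectra.append(RawSpectrum(catalog.chemical_ids[i], peaks))

    return catalog, spectra, emb, true_groups


def generate_worked_fixture() -> tuple[
    SensoryCatalog, list[RawSpectrum], EmbeddingTable, ClusterAssignment
]:
    """Tiny deterministic bundle with hand-checkable intermediate results.

    Six descriptors in two planted groups (floral: rose, lily, violet;
    dairy: milk, cheese, butter), eight chemicals, eight-bin spectra at
    m/z 51..58.  Chemical 0 carries only "rose", so its OR-label row is
    (floral=1, dairy=0); chemical 6 carries one descriptor of each group;
    chemical 7 carries none.
    """
    descriptors = ["rose", "lily", "violet", "milk", "cheese", "butter"]
    true_groups = ClusterAssignment(2, dict(zip(descriptors, [0, 0, 0, 1, 1, 1])))
    cat_matrix = np.array(
        [
            [1, 0, 0, 0, 0, 0],  # chem 0: rose only -> floral
            [0, 1, 0, 0, 0, 0],
            [0, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0, 1],
            [1, 0, 0, 1, 0, 0],  # chem 6: rose + milk -> both groups
            [0, 0, 0, 0, 0, 0],  # chem 7: odorless row
        ],
        dtype=np.int8,
    )
    catalog = SensoryCatalog(
        [f"chem{i}" for i in range(8)], descriptors, cat_matrix
    )
    vectors = {
        "rose": np.array([1.0, 0.0, 0.1, 0.0]),
        "lily": np.array([1.0, 0.1, 0.0, 0.0]),
        "violet": np.array([0.9, 0.0, 0.0, 0.1]),
        "milk": np.array([0.0, 1.0, 0.1, 0.0]),
        "cheese": np.array([0.1, 1.0, 0.0, 0.0]),
        "butter": np.array([0.0, 0.9, 0.0, 0.1]),
    }
    emb = EmbeddingTable(vectors, metadata={"source": "worked fixture"})
    floral_basis = np.array([4.0, 0.0, 3.0, 0.0, 0.0, 0.0, 1.0, 0.0])
    dairy_basis = np.array([0.0, 1.0, 0.0, 0.0, 3.0, 0.0, 0.0, 4.0])
    group_of = [0, 0, 0, 1, 1, 1]
    spectra = []
    for i in range(8):
        if i < 6:
            signal = (floral_basis if group_of[i] == 0 else dairy_basis) * (1.0 + 0.1 * i)
        elif i == 6:
            signal = floral_basis + dairy_basis
        else:
            signal = 0.5 * floral_basis + 0.5 * dairy_basis
        peaks = {SYNTH_MZ_LO + j: float(v) for j, v in enumerate(signal) if v > 0}
        spectra.append(RawSpectrum(f"chem{i}", peaks))
    return catalog, spectra, emb, true_groups
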