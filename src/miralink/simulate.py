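"""Synthetic input bundles with planted block structure.

The generator emulates the shape of curated disease-miRNA association
data, a functional gene network with log-likelihood edge scores, disease
gene sets, miRNA target/family/cluster annotations and a precomputed
miRNA-miRNA similarity matrix — all as plain TSV files.

The planted model is a partition of diseases and miRNAs into blocks:
same-block pairs associate with probability ``within_block_edge_prob``,
cross-block pairs with ``cross_block_edge_prob``.  Gene sets, LLS edges,
targets, families, clusters and the precomputed similarity matrix are all
aligned with the same blocks, so similarity features and network topology
both carry the planted signal.  Setting within == cross removes the signal
entirely (a null fixture).  Everything is reproducible under the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as mio
from .similarity import AssociationNetwork, GeneNetwork, SimilarityMatrix

__all__ = ["FixtureSpec", "FixtureBundle", "generate_tables", "generate_bilayer_fixture", "holdout_recovery_check"]


@dataclass(frozen=True)
class FixtureSpec:
    n_diseases: int = 30
    n_mirnas: int = 50
    n_genes: int = 150
    n_blocks: int = 3
    within_block_edge_prob: float = 0.5
    cross_block_edge_prob: float = 0.02
    gene_overlap_strength: float = 0.8
    genes_per_disease: int = 10
    target_pool_size: int = 240
    targets_per_mirna: int = 8
    family_size: int = 4
    cluster_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.within_block_edge_prob, self.cross_block_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability {p} outside [0, 1]")
        if self.cross_block_edge_prob > self.within_block_edge_prob:
            raise ValueError(
                "cross-block edge probability exceeds within-block probability: "
                "no planted signal is possible"
            )
        if min(self.n_diseases, self.n_mirnas, self.n_genes, self.n_blocks) < 1:
            raise ValueError("counts must be positive")
        if self.n_blocks > min(self.n_diseases, self.n_mirnas):
            raise ValueError("more blocks than diseases or miRNAs")


@dataclass
class FixtureBundle:
    """In-memory fixture: every table the pipeline consumes."""

    network: AssociationNetwork
    gene_network: GeneNetwork
    disease_genes: dict[str, set[str]]
    mirna_targets: dict[str, set[str]]
    mirna_families: dict[str, set[str]]
    mirna_clusters: dict[str, set[str]]
    rsd: SimilarityMatrix
    disease_blocks: dict[str, int]
    mirna_blocks: dict[str, int]
    spec: FixtureSpec


def _block_of(i: int, n: int, n_blocks: int) -> int:
    """Contiguous block assignment of item i among n items."""
    return min(i * n_blocks // n, n_blocks - 1)


def expected_edge_count(spec: FixtureSpec) -> float:
    """Closed-form expectation of the planted association-edge count."""
    d_blocks = [_block_of(i, spec.n_diseases, spec.n_blocks) for i in range(spec.n_diseases)]
    m_blocks = [_block_of(i, spec.n_mirnas, spec.n_blocks) for i in range(spec.n_mirnas)]
    same = sum(
        1 for bd in d_blocks for bm in m_blocks if bd == bm
    )
    total = spec.n_diseases * spec.n_mirnas
    return same * spec.within_block_edge_prob + (total - same) * spec.cross_block_edge_prob


def generate_tables(spec: FixtureSpec) -> FixtureBundle:
    rng = np.random.default_rng(spec.seed)
    diseases = [f"D{i:03d}" for i in range(spec.n_diseases)]
    mirnas = [f"R{i:03d}" for i in range(spec.n_mirnas)]
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    targets = [f"T{i:04d}" for i in range(spec.target_pool_size)]

    d_block = {d: _block_of(i, spec.n_diseases, spec.n_blocks) for i, d in enumerate(diseases)}
    m_block = {m: _block_of(i, spec.n_mirnas, spec.n_blocks) for i, m in enumerate(mirnas)}
    g_pool = [
        [g for i, g in enumerate(genes) if _block_of(i, spec.n_genes, spec.n_blocks) == b]
        for b in range(spec.n_blocks)
    ]
    t_pool = [
        [t for i, t in enumerate(targets) if _block_of(i, spec.target_pool_size, spec.n_blocks) == b]
        for b in range(spec.n_blocks)
    ]

    # bipartite associations: planted partition
    edges = {
        (d, m)
        for d in diseases
        for m in mirnas
        if rng.random()
        < (
            spec.within_block_edge_prob
            if d_block[d] == m_block[m]
            else spec.cross_block_edge_prob
        )
    }
    network = AssociationNetwork(diseases, mirnas, edges)

    # disease gene sets: mostly from the disease's block pool
    disease_genes: dict[str, set[str]] = {}
    for d in diseases:
        chosen: set[str] = set()
        pool = g_pool[d_block[d]]
        while len(chosen) < min(spec.genes_per_disease, spec.n_genes):
            if rng.random() < spec.gene_overlap_strength:
                chosen.add(pool[rng.integers(len(pool))])
            else:
                chosen.add(genes[rng.integers(len(genes))])
        disease_genes[d] = chosen

    # gene network: dense-ish within block pools, sparse across
    gnet = GeneNetwork()
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            same = _block_of(i, spec.n_genes, spec.n_blocks) == _block_of(
                j, spec.n_genes, spec.n_blocks
            )
            if rng.random() < (0.3 if same else 0.01):
                gnet.add_edge(genes[i], genes[j], float(rng.uniform(0.5, 2.0)))

    # miRNA target sets, block-aligned
    mirna_targets: dict[str, set[str]] = {}
    for m in mirnas:
        chosen = set()
        pool = t_pool[m_block[m]]
        while len(chosen) < min(spec.targets_per_mirna, spec.target_pool_size):
            if rng.random() < spec.gene_overlap_strength:
                chosen.add(pool[rng.integers(len(pool))])
            else:
                chosen.add(targets[rng.integers(len(targets))])
        mirna_targets[m] = chosen

    # families and clusters: within-block chunks of different sizes
    families: dict[str, set[str]] = {}
    clusters: dict[str, set[str]] = {}
    for b in range(spec.n_blocks):
        members = [m for m in mirnas if m_block[m] == b]
        for k, m in enumerate(members):
            families[m] = {f"F{b}_{k // max(spec.family_size, 1)}"}
            clusters[m] = {f"C{b}_{k // max(spec.cluster_size, 1)}"}

    # precomputed miRNA similarity (disease-derived stand-in): block
    # structure plus symmetric noise, clipped to [0, 1]
    h = spec.n_mirnas
    base = np.full((h, h), 0.1)
    for i, mi in enumerate(mirnas):
        for j, mj in enumerate(mirnas):
            if m_block[mi] == m_block[mj]:
                base[i, j] = 0.8
    noise = rng.normal(0.0, 0.1, size=(h, h))
    noise = (noise + noise.T) / 2.0
    rsd_values = np.clip(base + noise, 0.0, 1.0)
    np.fill_diagonal(rsd_values, 1.0)
    rsd = SimilarityMatrix(mirnas, rsd_values)

    return FixtureBundle(
        network, gnet, disease_genes, mirna_targets, families, clusters, rsd,
        d_block, m_block, spec,
    )


def generate_bilayer_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the full TSV bundle plus a manifest; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_tables(spec)

    paths = {
        "associations": outdir / "associations.tsv",
        "gene_network": outdir / "gene_network.tsv",
        "disease_genes": outdir / "disease_genes.tsv",
        "mirna_targets": outdir / "mirna_targets.tsv",
        "mirna_families": outdir / "mirna_families.tsv",
        "mirna_clusters": outdir / "mirna_clusters.tsv",
        "rsd_matrix": outdir / "rsd_matrix.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["associations"], "w") as fh:
        for d, m in sorted(bundle.network.edges):
            fh.write(f"{d}\t{m}\n")
    with open(paths["gene_network"], "w") as fh:
        seen = set()
        for a in sorted(bundle.gene_network._adj):
            for b, w in sorted(bundle.gene_network.neighbors(a).items()):
                if (b, a) not in seen:
                    seen.add((a, b))
                    fh.write(f"{a}\t{b}\t{w!r}\n")
    mio.save_memberships(bundle.disease_genes, paths["disease_genes"])
    mio.save_memberships(bundle.mirna_targets, paths["mirna_targets"])
    mio.save_memberships(bundle.mirna_families, paths["mirna_families"])
    mio.save_memberships(bundle.mirna_clusters, paths["mirna_clusters"])
    mio.save_similarity_matrix(bundle.rsd, paths["rsd_matrix"])
    with open(paths["manifest"], "w") as fh:
        json.dump({"spec": asdict(spec)}, fh, indent=2, sort_keys=True)
    return paths


def holdout_recovery_check(bundle: FixtureBundle, config=None, seed: int | None = None) -> dict:
    """Run the full pipeline under 5-fold CV on a fixture bundle.

    Returns mean AUC and top-10 precision/recall, per disease and overall;
    degenerate diseases (no positives) are skipped.
    """
    from .model import AssociationModel, PipelineConfig

    if config is None:
        config = PipelineConfig.compact()
    model = AssociationModel.from_tables(
        bundle.network,
        bundle.gene_network,
        bundle.disease_genes,
        bundle.mirna_targets,
        bundle.mirna_families,
        bundle.mirna_clusters,
        bundle.rsd,
        config=config,
    )
    results = model.fit(seed=seed)
    per_disease = results.disease_metrics()
    return {
        "mean_auc": results.mean_auc(),
        "mean_pre_at_10": float(per_disease["pre@10"].mean()),
        "mean_rec_at_10": float(per_disease["rec@10"].mean()),
        "n_diseases_evaluated": int(len(per_disease)),
        "per_disease": per_disease,
        "results": results,
    }
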