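"""Statsmodels-style front end: AssociationModel.fit() -> AssociationResults.

AssociationModel bundles the bilayer-network inputs (association edges,
gene network, disease gene sets, miRNA annotation tables, precomputed
miRNA similarity) with a PipelineConfig.  fit() runs the full procedure:

1. similarity matrices — disease DS from gene-set LLS aggregation, miRNA
   RS as the weighted RST/RSF/RSC/RSD combination;
2. per-disease five-fold CV — every disease's positives are dealt into
   five folds; fold f removes the union of fold-f edges from the network;
3. per fold — DeepWalk embeddings of the training network, similarity
   pair vectors compressed by a fold-local autoencoder, 1:1 negative
   sampling, two deep-forest classifiers (similarity features -> s1,
   topology features -> s2);
4. scoring — every candidate miRNA of each disease (all miRNAs not linked
   to it in the training network) receives s = lambda*s1 + (1-lambda)*s2;
   held-out positives vs. the remaining candidates give per-disease AUC
   and top-k precision/recall.

AssociationResults carries the score table, the per-disease/fold metrics,
a text summary() and candidate ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .autoencoder import AutoencoderSpec
from .deepwalk import WalkConfig, generate_walks, train_skipgram
from .evaluate import ScoreTable, fuse_scores, precision_recall_at_k, rank_candidates, roc_auc
from .features import (
    embedding_pair_vector,
    encode_pairs,
    pair_matrix,
    similarity_pair_vector,
    train_autoencoder,
)
from .forest import DeepForestConfig, fit_cascade, predict_scores
from .sampling import enumerate_unlabeled, make_disease_folds, sample_negatives
from .similarity import (
    AssociationNetwork,
    GeneNetwork,
    SimilarityMatrix,
    SimilarityWeights,
    combine_rs_matrix,
    compute_ds_matrix,
    compute_rst_matrix,
    membership_similarity,
)

__all__ = ["PipelineConfig", "AssociationModel", "AssociationResults"]

_MOD = 2**31  # derived seeds stay below 2^31


def _derive_seed(seed: int, *salts: int) -> int:
    out = seed % _MOD
    for salt in salts:
        out = (out * 1000003 + salt + 1) % _MOD
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the pipeline.

    Defaults follow the published operating point: similarity weights
    (0.2, 0.1, 0.2, 0.5), SkipGram window w=5, embedding dim n=128,
    autoencoder 913-512-256, scan window 100, four forests per cascade
    layer and fusion weight lambda=0.5.
    """

    weights: SimilarityWeights = SimilarityWeights()
    walk: WalkConfig = WalkConfig()
    ae_hidden: int = 512
    ae_latent: int = 256
    ae_epochs: int = 100
    forest: DeepForestConfig = DeepForestConfig()
    lam: float = 0.5
    cv_folds: int = 5
    lls_aggregation: str = "sum"
    rst_normalize: bool = True
    top_ks: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    @classmethod
    def compact(cls, seed: int = 0) -> "PipelineConfig":
        """Scaled-down operating point for small (tens-of-nodes) networks.

        Embedding dim 32, autoencoder hidden 48 / latent 32, scan window
        16 and lighter forests: appropriate when the similarity pair
        vector has ~100 rather than ~1000 coordinates.
        """
        return cls(
            walk=WalkConfig(dim=32, seed=seed),
            ae_hidden=48,
            ae_latent=32,
            ae_epochs=60,
            forest=DeepForestConfig(
                window=16, trees_per_forest=60, scan_trees=20, max_layers=2, seed=seed
            ),
            seed=seed,
        )

    def reseeded(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            seed=seed,
            walk=replace(self.walk, seed=seed),
            forest=replace(self.forest, seed=seed),
        )


class AssociationModel:
    """Disease-miRNA link-prediction model over a bilayer network."""

    def __init__(
        self,
        network: AssociationNetwork,
        gene_network: GeneNetwork,
        disease_genes: Mapping[str, set[str]],
        mirna_targets: Mapping[str, set[str]],
        mirna_families: Mapping[str, set[str]],
        mirna_clusters: Mapping[str, set[str]],
        rsd: SimilarityMatrix,
        config: PipelineConfig | None = None,
    ):
        self.network = network
        self.gene_network = gene_network
        self.disease_genes = {d: set(disease_genes.get(d, ())) for d in network.diseases}
        self.mirna_targets = dict(mirna_targets)
        self.mirna_families = dict(mirna_families)
        self.mirna_clusters = dict(mirna_clusters)
        self.rsd = rsd.subset(network.mirnas)
        self.config = config or PipelineConfig()
        self._ds: SimilarityMatrix | None = None
        self._rs: SimilarityMatrix | None = None

    # alternative constructors -------------------------------------------
    @classmethod
    def from_tables(cls, *args, **kwargs) -> "AssociationModel":
        """Alias of the constructor, for symmetry with from_directory."""
        return cls(*args, **kwargs)

    @classmethod
    def from_directory(
        cls, path: str | Path, config: PipelineConfig | None = None
    ) -> "AssociationModel":
        """Load a TSV bundle (the dialects written by the fixture generator)."""
        path = Path(path)
        required = [
            "associations.tsv", "gene_network.tsv", "disease_genes.tsv",
            "mirna_targets.tsv", "mirna_families.tsv", "mirna_clusters.tsv",
            "rsd_matrix.tsv",
        ]
        missing = [f for f in required if not (path / f).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files under {path}: {missing}")
        return cls(
            mio.load_associations(path / "associations.tsv"),
            mio.load_gene_network(path / "gene_network.tsv"),
            mio.load_membership_map(path / "disease_genes.tsv"),
            mio.load_membership_map(path / "mirna_targets.tsv"),
            mio.load_membership_map(path / "mirna_families.tsv"),
            mio.load_membership_map(path / "mirna_clusters.tsv"),
            mio.load_similarity_matrix(path / "rsd_matrix.tsv"),
            config=config,
        )

    # similarity layer ----------------------------------------------------
    @property
    def ds_matrix(self) -> SimilarityMatrix:
        if self._ds is None:
            self._ds = compute_ds_matrix(
                self.disease_genes,
                self.gene_network,
                self.network.diseases,
                aggregation=self.config.lls_aggregation,
            )
        return self._ds

    @property
    def rs_matrix(self) -> SimilarityMatrix:
        if self._rs is None:
            mirnas = self.network.mirnas
            rst = compute_rst_matrix(self.mirna_targets, mirnas, self.config.rst_normalize)
            rsf = membership_similarity(self.mirna_families, mirnas)
            rsc = membership_similarity(self.mirna_clusters, mirnas)
            self._rs = combine_rs_matrix(rst, rsf, rsc, self.rsd, self.config.weights)
        return self._rs

    # fitting -------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "AssociationResults":
        cfg = self.config if seed is None else self.config.reseeded(seed)
        seed = cfg.seed
        net = self.network
        ds, rs = self.ds_matrix, self.rs_matrix
        sim_width = net.n_diseases + net.n_mirnas
        ae_spec = AutoencoderSpec(
            input_dim=sim_width,
            hidden=cfg.ae_hidden,
            latent=cfg.ae_latent,
            epochs=cfg.ae_epochs,
        )

        plans = {
            d: make_disease_folds(net, d, _derive_seed(seed, 1, i), cfg.cv_folds)
            for i, d in enumerate(net.diseases)
        }
        skipped = [d for d in net.diseases if not net.mirnas_of(d)]
        if skipped:
            warnings.warn(
                f"{len(skipped)} disease(s) without positives are skipped: {skipped[:5]}",
                stacklevel=2,
            )
        unlabeled_full = enumerate_unlabeled(net)

        score_rows: list[dict] = []
        metric_rows: list[dict] = []
        for fold in range(cfg.cv_folds):
            held: set[tuple[str, str]] = set()
            for plan in plans.values():
                held |= plan.held_out(fold)
            train_net = net.without_edges(held)
            train_pos = sorted(train_net.edges)
            negatives = sample_negatives(
                unlabeled_full, len(train_pos), _derive_seed(seed, 2, fold)
            )
            train_pairs = train_pos + sorted(negatives)
            y = np.array([1] * len(train_pos) + [0] * len(negatives), dtype=int)

            # topology features: walks + SkipGram on the training network
            wcfg = replace(cfg.walk, seed=_derive_seed(seed, 3, fold))
            phi = train_skipgram(generate_walks(train_net, wcfg), wcfg)

            # similarity features, compressed by a fold-local autoencoder
            sim_train = [similarity_pair_vector(d, m, ds, rs) for d, m in train_pairs]
            encoder = train_autoencoder(
                sim_train, replace(ae_spec, seed=_derive_seed(seed, 4, fold))
            )
            X_sim = pair_matrix(encode_pairs(sim_train, encoder))
            X_dw = pair_matrix(
                [embedding_pair_vector(d, m, phi) for d, m in train_pairs]
            )

            fcfg = replace(cfg.forest, seed=_derive_seed(seed, 5, fold))
            model_sim = fit_cascade(X_sim, y, fcfg)
            fcfg2 = replace(cfg.forest, seed=_derive_seed(seed, 6, fold))
            model_dw = fit_cascade(X_dw, y, fcfg2)

            # candidates: per disease, every miRNA not linked in training
            test_pairs: list[tuple[str, str]] = []
            for d in net.diseases:
                if not plans[d].held_out(fold):
                    continue
                linked = {m for dd, m in train_net.edges if dd == d}
                test_pairs.extend((d, m) for m in net.mirnas if m not in linked)
            if not test_pairs:
                continue
            sim_test = [similarity_pair_vector(d, m, ds, rs) for d, m in test_pairs]
            Xt_sim = pair_matrix(encode_pairs(sim_test, encoder))
            Xt_dw = pair_matrix(
                [embedding_pair_vector(d, m, phi) for d, m in test_pairs]
            )
            s1 = predict_scores(model_sim, Xt_sim)
            s2 = predict_scores(model_dw, Xt_dw)
            s = fuse_scores(s1, s2, cfg.lam)
            labels = np.array(
                [1 if pair in net.edges else 0 for pair in test_pairs], dtype=int
            )
            for (d, m), a, b, c, lab in zip(test_pairs, s1, s2, s, labels):
                score_rows.append(
                    {"fold": fold, "disease": d, "mirna": m, "label": int(lab),
                     "s1": float(a), "s2": float(b), "s": float(c)}
                )

            # per-disease metrics within this fold
            frame = pd.DataFrame(score_rows[-len(test_pairs):])
            for d, sub in frame.groupby("disease", sort=True):
                lab = sub["label"].to_numpy()
                if lab.sum() == 0 or lab.sum() == len(lab):
                    continue
                auc = roc_auc(lab, sub["s"].to_numpy())
                order = sub.sort_values(["s", "mirna"], ascending=[False, True])
                ranked = order["mirna"].tolist()
                held_set = set(order.loc[order["label"] == 1, "mirna"])
                row = {"fold": fold, "disease": d, "auc": auc,
                       "n_held_out": int(lab.sum()), "n_candidates": int(len(lab))}
                for k in cfg.top_ks:
                    pre, rec = precision_recall_at_k(ranked, held_set, k)
                    row[f"pre@{k}"] = pre
                    row[f"rec@{k}"] = rec
                metric_rows.append(row)

        scores = pd.DataFrame(
            score_rows, columns=["fold", "disease", "mirna", "label", "s1", "s2", "s"]
        ).sort_values(["fold", "disease", "mirna"], kind="mergesort").reset_index(drop=True)
        metrics = pd.DataFrame(metric_rows)
        return AssociationResults(self, cfg, scores, metrics)


@dataclass
class AssociationResults:
    """Fitted-pipeline results: scores, CV metrics, ranking and summary."""

    model: AssociationModel
    config: PipelineConfig
    scores: pd.DataFrame  # fold, disease, mirna, label, s1, s2, s
    metrics: pd.DataFrame  # fold, disease, auc, pre@k, rec@k
    _table: ScoreTable = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._table = ScoreTable(self.scores, self.config.lam)

    # metrics -------------------------------------------------------------
    def disease_metrics(self) -> pd.DataFrame:
        """Fold-averaged metrics per disease (AUC, pre@k, rec@k)."""
        if self.metrics.empty:
            return pd.DataFrame(columns=["auc"])
        return self.metrics.drop(columns=["fold"]).groupby("disease", sort=True).mean()

    def mean_auc(self) -> float:
        per_disease = self.disease_metrics()
        if per_disease.empty:
            raise ValueError("no disease could be evaluated")
        return float(per_disease["auc"].mean())

    # ranking -------------------------------------------------------------
    def rank_candidates(self, disease: str, top_k: int | None = None) -> pd.DataFrame:
        """Candidates of one disease ranked by mean fused score across folds.

        Columns: rank, mirna, s1, s2, s — the per-disease ranked-candidate
        table shape (evidence columns excluded).
        """
        if disease not in self.model.network.diseases:
            raise KeyError(
                f"unknown disease {disease!r}; known: {self.model.network.diseases[:10]}..."
            )
        sub = (
            self.scores[self.scores["disease"] == disease]
            .groupby("mirna", sort=True)[["s1", "s2", "s"]]
            .mean()
            .reset_index()
        )
        agg = ScoreTable(sub.assign(disease=disease), self.config.lam)
        ranked = rank_candidates(agg, disease)
        sub = sub.set_index("mirna").loc[ranked].reset_index()
        sub.insert(0, "rank", np.arange(1, len(sub) + 1))
        if top_k is not None:
            sub = sub.head(top_k)
        return sub[["rank", "mirna", "s1", "s2", "s"]]

    # output --------------------------------------------------------------
    def save_scores(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index=False, float_format="%.10f")

    def summary(self) -> str:
        per_disease = self.disease_metrics()
        lines = [
            "Disease-miRNA association prediction (similarity + topology fusion)",
            "=" * 68,
            f"diseases: {self.model.network.n_diseases}   "
            f"miRNAs: {self.model.network.n_mirnas}   "
            f"known associations: {len(self.model.network.edges)}",
            f"CV folds: {self.config.cv_folds}   lambda: {self.config.lam}   "
            f"seed: {self.config.seed}",
            f"diseases evaluated: {len(per_disease)}",
            f"mean AUC: {per_disease['auc'].mean():.4f}",
        ]
        for k in self.config.top_ks[:3]:
            col = f"pre@{k}"
            if col in per_disease:
                lines.append(
                    f"mean PRE@{k}: {per_disease[col].mean():.4f}   "
                    f"mean REC@{k}: {per_disease[f'rec@{k}'].mean():.4f}"
                )
        lines.append("-" * 68)
        top = per_disease["auc"].sort_values(ascending=False).head(10)
        lines.append("top diseases by AUC:")
        for d, a in top.items():
            lines.append(f"  {d:<20s} {a:.4f}")
        return "\n".join(lines)
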