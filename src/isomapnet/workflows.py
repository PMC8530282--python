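"""High-level experiment workflows over the synthetic isoform-switch data.

These functions chain the modules into the canonical experiments: normalize
counts, split samples, train the exon-level network with an isoform map
layer next to a gene-level network, and score both on the held-out test
set.  They are used by the command line, the test suite and the
reproduction script alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess as pp
from .evaluation import roc_auc
from .netlayers import LayerSpec, Network, NetworkSpec, build_network
from .synthetic import SyntheticDataset, SyntheticSpec, generate
from .training import TrainingConfig, train

__all__ = [
    "normalized_expression",
    "SplitData",
    "split_xy",
    "train_exon_model",
    "train_gene_model",
    "exon_vs_gene_auc",
    "sparse_recovery",
]


def normalized_expression(counts: pp.CountMatrix) -> pp.ExpressionMatrix:
    """TMM factors, log2-CPM, then quantile normalization."""
    factors = pp.tmm_factors(counts)
    return pp.quantile_normalize(pp.log2_cpm(counts, factors))


@dataclass
class SplitData:
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


def split_xy(
    expr: pp.ExpressionMatrix,
    samples: pp.SampleTable,
    split: pp.SplitAssignment,
    standardize: bool = True,
) -> SplitData:
    """Assemble per-split sample x feature arrays from an expression matrix.

    With ``standardize`` (the default for network training), features are
    centered and scaled using training-split statistics only; log2-CPM
    values have means far from zero, which would otherwise saturate the
    sigmoid at initialization.
    """
    X = expr.values.T
    pos = {s: i for i, s in enumerate(expr.sample_ids)}
    out = {}
    for name, attr in (("train", "train"), ("validation", "val"), ("test", "test")):
        idx = [pos[s] for s in split.samples_in(name)]
        out[f"X_{attr}"] = X[idx]
        out[f"y_{attr}"] = samples.labels_for([expr.sample_ids[i] for i in idx])
    if standardize:
        mu = out["X_train"].mean(axis=0)
        sd = out["X_train"].std(axis=0)
        sd[sd == 0] = 1.0
        for attr in ("train", "val", "test"):
            out[f"X_{attr}"] = (out[f"X_{attr}"] - mu) / sd
    return SplitData(**out)


def _default_split(ds: SyntheticDataset, seed: int) -> pp.SplitAssignment:
    n = len(ds.samples.sample_ids)
    n_test = n // 5
    n_val = n // 5
    return pp.split_dataset(ds.samples, (n - n_val - n_test, n_val, n_test), seed=seed)


def train_exon_model(
    ds: SyntheticDataset,
    split: pp.SplitAssignment,
    config: TrainingConfig,
    hidden: int = 32,
    use_fsl: bool = True,
    use_iml: bool = True,
) -> tuple[Network, SplitData]:
    """Train the exon-level classifier (optionally FSL and IML) and return it."""
    expr = normalized_expression(ds.exon_counts)
    data = split_xy(expr, ds.samples, split)
    layers: list[LayerSpec] = []
    masks = {}
    if use_fsl:
        layers.append(LayerSpec("fsl"))
    if use_iml:
        masks[len(layers)] = ds.annotation.iso_map
        layers.append(LayerSpec("iml"))
    layers.append(LayerSpec("dense", hidden))
    spec = NetworkSpec(input_dim=expr.values.shape[0], layers=layers,
                       dropout_rate=config.dropout)
    model = build_network(spec, masks=masks, seed=config.seed,
                          feature_ids=expr.feature_ids, fsl_l1=config.fsl_l1)
    model, _ = train(model, (data.X_train, data.y_train),
                     (data.X_val, data.y_val), config)
    return model, data


def train_gene_model(
    ds: SyntheticDataset,
    split: pp.SplitAssignment,
    config: TrainingConfig,
    hidden: int = 32,
) -> tuple[Network, SplitData]:
    """Train the gene-level classifier (plain dense stack) on gene counts."""
    expr = normalized_expression(ds.gene_counts)
    data = split_xy(expr, ds.samples, split)
    spec = NetworkSpec(
        input_dim=expr.values.shape[0],
        layers=[LayerSpec("dense", hidden)],
        dropout_rate=config.dropout,
    )
    model = build_network(spec, seed=config.seed, feature_ids=expr.feature_ids)
    model, _ = train(model, (data.X_train, data.y_train),
                     (data.X_val, data.y_val), config)
    return model, data


def exon_vs_gene_auc(spec: SyntheticSpec) -> dict[str, float]:
    """Held-out test AUC of the exon+IML+FSL model versus the gene model.

    One dataset is generated from ``spec``; both models share the same
    label-stratified 60/20/20 split and training protocol.
    """
    ds = generate(spec)
    split = _default_split(ds, seed=spec.seed)
    config = TrainingConfig(seed=spec.seed)
    exon_model, exon_data = train_exon_model(ds, split, config)
    gene_model, gene_data = train_gene_model(ds, split, config)
    return {
        "exon_auc": roc_auc(exon_model.predict_proba(exon_data.X_test),
                            exon_data.y_test),
        "gene_auc": roc_auc(gene_model.predict_proba(gene_data.X_test),
                            gene_data.y_test),
        "n_test": float(exon_data.y_test.size),
    }


def sparse_recovery(
    spec: SyntheticSpec, q: float = 0.2, method: str = "fsl"
) -> dict[str, float]:
    """Recall of planted informative exons inside the top-``q`` importance set.

    Trains the exon FSL+IML model on a dataset from ``spec`` and scores
    every exon either by its learned feature-selection weight (``fsl``, the
    default: the FSL exists precisely to expose per-feature importance) or
    by mean absolute saliency over the training samples (``saliency``).
    Reports which fraction of the truly informative exons lands in the top
    ``q`` of scores; chance level is ``q``.
    """
    from .interpret import fsl_importance, saliency_importance, top_fraction

    ds = generate(spec)
    split = _default_split(ds, seed=spec.seed)
    config = TrainingConfig(seed=spec.seed)
    model, data = train_exon_model(ds, split, config)
    if method == "fsl":
        importance = fsl_importance(model, model.feature_ids)
    else:
        importance = saliency_importance(model, data.X_train, model.feature_ids)
    selected = top_fraction(importance, q=q)
    informative = set(ds.truth["informative_exons"])
    recall = len(selected & informative) / len(informative)
    return {
        "recall": recall,
        "n_informative": float(len(informative)),
        "n_selected": float(len(selected)),
        "n_features": float(len(importance)),
    }
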