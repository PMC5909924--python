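"""Model interpretation: gradient-based feature importance, hidden-node
contribution scores, and node-gene correlations for downstream enrichment.

Feature importance is the partial derivative of the prognostic index with
respect to each input, averaged over patients; for the zero-hidden-layer
model this is exactly the Cox coefficient vector, which anchors the scores
to the classical interpretation.  A hidden node's contribution to a patient
is its activation times its output-layer coefficient, so the contributions
sum column-wise to the prognostic index — an exact additive decomposition
that lets nodes act as survival-sensitive reduced dimensions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .network import SurvivalNet

__all__ = [
    "ImportanceScores",
    "NodeContributions",
    "feature_importance",
    "node_contributions",
    "top_variance_nodes",
    "node_gene_correlation",
    "export_ranked_lists",
]


@dataclass
class ImportanceScores:
    """Average partial derivatives of the model output w.r.t. each input."""

    per_feature: np.ndarray  # (J,)
    per_node_per_feature: np.ndarray | None  # (H, J), single-hidden-layer models
    feature_names: list[str] | None = None


@dataclass
class NodeContributions:
    """(H, n) matrix: node h's activation x beta_h for each patient.

    Columns sum exactly to the prognostic index.
    """

    contributions: np.ndarray


def _eval_scale(model: SurvivalNet) -> float:
    return model.dropout_p if model.dropout_p < 1.0 else 1.0


def feature_importance(model: SurvivalNet, X: np.ndarray) -> ImportanceScores:
    """Per-gene importance: mean over patients of d(theta)/d(x_j).

    Derivatives are taken through the deterministic eval-mode network
    (dropout applied as activation scaling).  For a model with hidden
    layers the chain rule gives, per patient,
    ``d theta / d x = W^T diag(p (1 - tanh^2)) beta`` (composed across
    layers); with no hidden layer the derivative is beta itself.
    """
    X = np.asarray(X, dtype=float)
    _, _, raw = model._forward_cached(X, "eval", None)
    scale = _eval_scale(model)
    n = X.shape[0]
    if model.n_hidden_layers == 0:
        per_feature = model.beta.copy()
        per_node = None
    else:
        D = np.broadcast_to(model.beta, (n, model.beta.shape[0]))
        for layer in range(model.n_hidden_layers - 1, -1, -1):
            D = (D * scale * (1.0 - raw[layer] ** 2)) @ model.weights[layer]
        per_feature = D.mean(axis=0)
        if model.n_hidden_layers == 1:
            # d a_h / d x_j = p (1 - tanh^2) W_hj, averaged over patients
            per_node = (scale * (1.0 - raw[0] ** 2)).mean(axis=0)[:, None] * model.weights[0]
        else:
            per_node = None
    return ImportanceScores(
        per_feature=per_feature,
        per_node_per_feature=per_node,
        feature_names=model.feature_names,
    )


def node_contributions(model: SurvivalNet, X: np.ndarray) -> NodeContributions:
    """Hidden-node contribution matrix (activation x output coefficient)."""
    if model.n_hidden_layers < 1:
        raise ValueError("node contributions require at least one hidden layer")
    _, acts = model.forward(np.asarray(X, dtype=float), mode="eval")
    contrib = (acts[-1] * model.beta).T
    return NodeContributions(contributions=contrib)


def top_variance_nodes(contributions: NodeContributions | np.ndarray, k: int = 20) -> np.ndarray:
    """Indices of the k nodes with the largest across-patient variance,
    descending; ties resolved toward the lower index."""
    C = contributions.contributions if isinstance(contributions, NodeContributions) else np.asarray(contributions)
    if k > C.shape[0]:
        raise ValueError(f"k={k} exceeds the number of nodes {C.shape[0]}")
    var = C.var(axis=1)
    order = np.argsort(-var, kind="stable")  # stable: equal variances keep index order
    return order[:k]


def node_gene_correlation(ds: SurvivalDataset, node_outputs: np.ndarray) -> np.ndarray:
    """Pearson correlation of each gene with each node output, (H, J).

    ``node_outputs`` is (n_patients, H) — e.g. the hidden activations or the
    contribution matrix transposed.  Zero-variance genes or nodes give NaN.
    """
    Y = np.asarray(node_outputs, dtype=float)
    X = ds.X
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("node_outputs rows must match the number of patients")
    if n < 3:
        raise ValueError("need at least 3 patients for a meaningful correlation")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = Yc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Yc.T @ Xc) / n / np.outer(sy, sx)
    corr[:, sx == 0] = np.nan
    corr[sy == 0, :] = np.nan
    return corr


def export_ranked_lists(
    corr: np.ndarray, feature_names: list[str], outdir: str, prefix: str = "node"
) -> list[str]:
    """Write one two-column ranked list per node (gene, r; descending r),
    the preranked input format of enrichment tools.  NaN genes are dropped."""
    os.makedirs(outdir, exist_ok=True)
    names = np.asarray(feature_names)
    paths = []
    for h in range(corr.shape[0]):
        r = corr[h]
        keep = np.isfinite(r)
        order = np.argsort(-r[keep], kind="stable")
        path = os.path.join(outdir, f"{prefix}{h}.rnk")
        with open(path, "w", encoding="utf-8") as fh:
            for gene, val in zip(names[keep][order], r[keep][order]):
                fh.write(f"{gene}\t{val:.10g}\n")
        paths.append(path)
    return paths
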