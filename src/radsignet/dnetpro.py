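"""DNetPRO: discriminant-network feature-signature extraction.

The algorithm scores every unordered feature couple with a linear
maximum-margin classifier under stratified inner cross-validation, keeps the
best-scoring couples, builds a graph whose connected components are
candidate signatures, and evaluates each component with an L2-penalized
logistic model.  Couples matter because two individually weak features can
be jointly discriminative — a structure single-feature ranking cannot see.

Two selection procedures are provided:

* **procedure A** — couples are scored, the network built, and components
  evaluated inside each outer training split; the winning component is
  refitted and scored on the outer test fold.  The consensus signature is
  the component winning the most outer splits.
* **procedure B** — a stratified three-way hold-out: couples and network on
  the training third, component ranking on the validation third, final
  scoring on the test third, with the three parts rotated through all roles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._seeds import derive_seed
from .evaluation import mcc_score

__all__ = [
    "DNetProConfig",
    "CoupleScore",
    "SignatureNetwork",
    "Signature",
    "score_couples",
    "build_network",
    "evaluate_signature",
    "procedure_a",
    "procedure_b",
    "export_signature",
]


class TooManyFeaturesError(ValueError):
    """Couple scoring is quadratic; refuse very wide inputs."""


class PartitionError(ValueError):
    """Not enough samples per class for the requested partitioning."""


@dataclass(frozen=True)
class DNetProConfig:
    """Tunable parameters of the signature-extraction procedures.

    ``keep_fraction`` retains the top fraction of couples by score
    (percentile rule); setting ``score_threshold`` switches to a hard
    score cut-off instead.  ``penalty`` is the L2 strength (lambda) of the
    logistic models, i.e. C = 1 / penalty on standardized inputs.
    """

    inner_folds: int = 5
    eval_folds: int = 5
    outer_folds: int = 10
    keep_fraction: float = 0.05
    score_threshold: float | None = None
    penalty: float = 1.0
    metric: str = "mcc"
    svm_C: float = 1.0
    p_max: int = 2000
    b_independent_partitions: bool = False
    seed: int = 0


@dataclass(frozen=True)
class CoupleScore:
    i: int
    j: int
    score: float


@dataclass
class SignatureNetwork:
    """Weighted feature graph; connected components are candidate signatures."""

    feature_names: list[str]
    edges: list[tuple[int, int, float]]
    components: list[list[int]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        used = sorted({v for i, j, _ in self.edges for v in (i, j)})
        g.add_nodes_from(self.feature_names[v] for v in used)
        g.add_weighted_edges_from(
            (self.feature_names[i], self.feature_names[j], w) for i, j, w in self.edges)
        return g


@dataclass
class Signature:
    """A selected feature subset plus its couple network."""

    features: list[str]
    network: SignatureNetwork
    eval_score: float
    procedure: str


def _metric_fn(metric: str):
    if metric == "mcc":
        return mcc_score
    if metric == "accuracy":
        return lambda yt, yp: float(np.mean(np.asarray(yt) == np.asarray(yp)))
    raise ValueError(f"unknown couple metric {metric!r}")


def score_couples(X, y, inner_folds: int = 5, metric: str = "mcc", seed: int = 0,
                  svm_C: float = 1.0, p_max: int = 2000) -> list[CoupleScore]:
    """Score all C(p, 2) feature couples with a linear SVM under stratified CV.

    For every unordered pair the classifier is fitted on the pair's two
    columns within each inner training fold and the mean out-of-fold score
    (MCC by default) is recorded.  Deterministic under ``seed`` (the fold
    draw is the only random element and is shared by all pairs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least two features to form couples")
    if p > p_max:
        raise TooManyFeaturesError(
            f"{p} features would give {p * (p - 1) // 2} couples; pre-filter to a "
            f"single radiomic category or raise p_max (currently {p_max})")
    score = _metric_fn(metric)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*least populated class.*")
        splits = list(skf.split(X, y))
    folds = []
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2:
            warnings.warn("skipping an inner fold whose training part lost one "
                          "class (very small stratum)", stacklevel=2)
            continue
        folds.append((np.asfortranarray(X[tr]), y[tr], np.asfortranarray(X[te]), y[te]))
    if not folds:
        raise ValueError("every inner training fold lost one class; "
                         "use fewer inner folds")
    couples: list[CoupleScore] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(p - 1):
            for j in range(i + 1, p):
                total = 0.0
                for Xtr, ytr, Xte, yte in folds:
                    clf = LinearSVC(C=svm_C).fit(Xtr[:, [i, j]], ytr)
                    total += score(yte, clf.predict(Xte[:, [i, j]]))
                couples.append(CoupleScore(i, j, total / len(folds)))
    return couples


def build_network(couples: list[CoupleScore], keep_fraction: float = 0.05,
                  feature_names: list[str] | None = None,
                  score_threshold: float | None = None) -> SignatureNetwork:
    """Keep the top couples and return the resulting feature graph.

    Retains the top ``ceil(keep_fraction * len(couples))`` couples by score
    (ties broken by score, then lower i, then lower j, so retention is a
    deterministic prefix and monotone in ``keep_fraction``); with
    ``score_threshold`` set, retains couples scoring at or above it instead.
    Nodes are the endpoints of retained couples; components come from
    standard graph reachability.
    """
    if not couples:
        raise ValueError("empty couple list")
    if score_threshold is None and not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    ordered = sorted(couples, key=lambda c: (-c.score, c.i, c.j))
    if score_threshold is not None:
        retained = [c for c in ordered if c.score >= score_threshold]
        if not retained:
            retained = ordered[:1]  # never return an empty network
    else:
        retained = ordered[: math.ceil(keep_fraction * len(couples))]
    n_feat = max(max(c.i, c.j) for c in couples) + 1
    if feature_names is None:
        feature_names = [f"f{k}" for k in range(n_feat)]
    g = nx.Graph()
    g.add_edges_from((c.i, c.j) for c in retained)
    components = sorted((sorted(comp) for comp in nx.connected_components(g)),
                        key=lambda comp: (-len(comp), comp))
    return SignatureNetwork(list(feature_names),
                            [(c.i, c.j, c.score) for c in retained], components)


def evaluate_signature(X_sub, y, cv_folds: int = 5, penalty: float = 1.0,
                       seed: int = 0) -> float:
    """Cross-validated MCC of an L2-penalized logistic model on a component."""
    X_sub = np.asarray(X_sub, dtype=float)
    if X_sub.ndim == 1:
        X_sub = X_sub[:, None]
    if X_sub.shape[1] < 1:
        raise ValueError("component must contain at least one feature")
    y = np.asarray(y).astype(int)
    n_folds = min(cv_folds, int(np.bincount(y, minlength=2).min()))
    skf = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X_sub, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue  # degenerate fold, skipped
        clf = _logistic(penalty).fit(X_sub[tr], y[tr])
        scores.append(mcc_score(y[te], clf.predict(X_sub[te])))
    if not scores:
        raise ValueError("every fold was degenerate; cannot evaluate component")
    return float(np.mean(scores))


def _logistic(penalty: float) -> LogisticRegression:
    # ridge-penalized logistic model: L2 is the estimator's default penalty
    return LogisticRegression(C=1.0 / penalty, max_iter=2000)


def _best_component(net: SignatureNetwork, X, y, config: DNetProConfig,
                    seed: int) -> tuple[list[int], float, dict[tuple[int, ...], float]]:
    evals: dict[tuple[int, ...], float] = {}
    for comp in net.components:
        evals[tuple(comp)] = evaluate_signature(
            X[:, comp], y, config.eval_folds, config.penalty, seed)
    best = max(net.components,
               key=lambda comp: (evals[tuple(comp)], -len(comp),
                                 [net.feature_names[i] for i in comp]))
    return best, evals[tuple(best)], evals


def _subnetwork(net: SignatureNetwork, comp: list[int]) -> SignatureNetwork:
    comp_set = set(comp)
    edges = [(i, j, w) for i, j, w in net.edges if i in comp_set and j in comp_set]
    return SignatureNetwork(net.feature_names, edges, [sorted(comp)])


def _ordered_features(sub: SignatureNetwork, comp: list[int]) -> list[str]:
    g = nx.Graph()
    g.add_nodes_from(comp)
    g.add_edges_from((i, j) for i, j, _ in sub.edges)
    return [sub.feature_names[i]
            for i in sorted(comp, key=lambda i: (-g.degree(i), sub.feature_names[i]))]


def _scaled(train_X, *others):
    scaler = StandardScaler().fit(train_X)
    return [scaler.transform(train_X)] + [scaler.transform(o) for o in others]


def procedure_a(X, y, feature_names: list[str] | None = None,
                config: DNetProConfig = DNetProConfig()) -> tuple[Signature, "CVResult"]:
    """Outer-CV DNetPRO selection; returns the consensus signature and the
    outer-test MCC distribution.

    Within each outer training split: standardize, score couples, build the
    network, evaluate every component on the training data and refit the
    winner, then score the outer test fold.  The consensus signature is the
    component winning most outer splits (ties by mean evaluation score).
    """
    from .evaluation import CVResult

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if feature_names is None:
        feature_names = [f"f{k}" for k in range(X.shape[1])]
    skf = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                          random_state=config.seed)
    outer_scores: list[float] = []
    wins: dict[tuple[str, ...], list[tuple[float, SignatureNetwork, list[int]]]] = {}
    for k, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = _scaled(X[tr], X[te])
        couples = score_couples(Xtr, y[tr], config.inner_folds, config.metric,
                                derive_seed(config.seed, f"couples{k}"),
                                config.svm_C, config.p_max)
        net = build_network(couples, config.keep_fraction, feature_names,
                            config.score_threshold)
        comp, comp_eval, _ = _best_component(net, Xtr, y[tr], config,
                                             derive_seed(config.seed, f"eval{k}"))
        clf = _logistic(config.penalty).fit(Xtr[:, comp], y[tr])
        outer_scores.append(mcc_score(y[te], clf.predict(Xte[:, comp])))
        key = tuple(sorted(feature_names[i] for i in comp))
        wins.setdefault(key, []).append((comp_eval, _subnetwork(net, comp), comp))

    best_key = max(wins, key=lambda k: (len(wins[k]),
                                        float(np.mean([e for e, _, _ in wins[k]])), k))
    candidates = wins[best_key]
    best_eval, best_net, best_comp = max(candidates, key=lambda t: t[0])
    signature = Signature(_ordered_features(best_net, best_comp), best_net,
                          float(np.mean([e for e, _, _ in candidates])), "A")
    result = CVResult(np.array(outer_scores), 1, config.outer_folds,
                      "dnetpro_A", config.seed)
    return signature, result


def procedure_b(X, y, feature_names: list[str] | None = None,
                config: DNetProConfig = DNetProConfig()) -> tuple[Signature, "CVResult"]:
    """Three-way hold-out DNetPRO selection.

    The cohort is split into three stratified parts which rotate through the
    train / validation / test roles over three iterations: couples and
    network are derived on the training part, components are ranked by
    validation MCC, and the winning component (refitted on train +
    validation) is scored on the test part.  Returns the best signature
    across iterations (by validation score) and the three test MCCs.
    """
    from .evaluation import CVResult

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.bincount(y, minlength=2).min() < 3:
        raise PartitionError("stratified thirds need at least 3 samples per class")
    if feature_names is None:
        feature_names = [f"f{k}" for k in range(X.shape[1])]

    def parts_for(rotation: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        part_seed = (derive_seed(config.seed, f"partition{rotation}")
                     if config.b_independent_partitions else config.seed)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=part_seed)
        folds = [te for _, te in skf.split(X, y)]
        return (folds[rotation % 3], folds[(rotation + 1) % 3], folds[(rotation + 2) % 3])

    test_scores: list[float] = []
    candidates: list[tuple[float, int, SignatureNetwork, list[int]]] = []
    for rotation in range(3):
        test_idx, val_idx, train_idx = parts_for(rotation)
        Xtr, Xval = _scaled(X[train_idx], X[val_idx])
        couples = score_couples(Xtr, y[train_idx], config.inner_folds, config.metric,
                                derive_seed(config.seed, f"b_couples{rotation}"),
                                config.svm_C, config.p_max)
        net = build_network(couples, config.keep_fraction, feature_names,
                            config.score_threshold)
        ranked = []
        for comp in net.components:
            clf = _logistic(config.penalty).fit(Xtr[:, comp], y[train_idx])
            val_mcc = mcc_score(y[val_idx], clf.predict(Xval[:, comp]))
            ranked.append((val_mcc, comp))
        val_score, comp = max(
            ranked, key=lambda t: (t[0], -len(t[1]),
                                   [feature_names[i] for i in t[1]]))
        dev_idx = np.concatenate([train_idx, val_idx])
        Xdev, Xtest = _scaled(X[dev_idx], X[test_idx])
        clf = _logistic(config.penalty).fit(Xdev[:, comp], y[dev_idx])
        test_scores.append(mcc_score(y[test_idx], clf.predict(Xtest[:, comp])))
        candidates.append((val_score, -rotation, _subnetwork(net, comp), comp))

    val_score, neg_rot, best_net, best_comp = max(candidates, key=lambda t: (t[0], t[1]))
    signature = Signature(_ordered_features(best_net, best_comp), best_net,
                          float(val_score), "B")
    result = CVResult(np.array(test_scores), 3, 3, "dnetpro_B", config.seed)
    return signature, result


def export_signature(signature: Signature, outdir: str | Path,
                     basename: str = "signature") -> dict[str, Path]:
    """Write the signature network as GraphML plus edge and node CSV tables.

    The node table carries the normalized degree centrality (degree / (n-1));
    the maximum-centrality node(s) are flagged as hubs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = signature.network.to_networkx()
    for name in signature.features:
        if name not in g:
            g.add_node(name)
    centrality = (nx.degree_centrality(g) if g.number_of_nodes() > 1
                  else {n: 0.0 for n in g})
    max_c = max(centrality.values()) if centrality else 0.0
    nx.set_node_attributes(g, centrality, "degree_centrality")

    paths = {"graphml": outdir / f"{basename}.graphml",
             "edges": outdir / f"{basename}_edges.csv",
             "nodes": outdir / f"{basename}_nodes.csv"}
    nx.write_graphml(g, paths["graphml"])
    pd.DataFrame(
        [{"source": u, "target": v, "score": d.get("weight", np.nan)}
         for u, v, d in sorted(g.edges(data=True))]
    ).to_csv(paths["edges"], index=False)
    pd.DataFrame(
        [{"feature": n, "degree": g.degree(n),
          "degree_centrality": centrality.get(n, 0.0),
          "is_hub": bool(max_c > 0 and centrality.get(n, 0.0) == max_c)}
         for n in sorted(g.nodes)]
    ).to_csv(paths["nodes"], index=False)
    return paths
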