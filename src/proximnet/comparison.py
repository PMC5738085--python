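"""Cross-modality network comparison.

Networks from different measurement modalities (app, badge, survey) are
compared with a Mantel test: the Spearman correlation of the two
upper-triangle dyad weight vectors, with significance from simultaneous
row/column relabelings of one matrix and a bootstrap percentile CI over
dyads.  Weighted proximity networks are reduced to binary backbones with
the disparity filter — an edge survives when its normalised weight
p = w/s is improbable under a uniform split of its endpoint's strength s
over its k edges, alpha = (1 - p)^(k - 1) — with the significance level
swept so the backbone's density matches the (survey) reference network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    SurveyResponse,
    UndefinedStatisticError,
    ValidationError,
    WeightedNetwork,
)


def collapse_directed(
    responses: list[SurveyResponse], nodes: tuple[str, ...] | list[str]
) -> WeightedNetwork:
    """Collapse directed survey nominations into a binary undirected net.

    Edge {i, j} is present iff i nominated j or j nominated i.
    Nominations of non-enrolled alters are ignored.
    """
    nodes = tuple(nodes)
    idx = {p: i for i, p in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for r in responses:
        if r.ego not in idx:
            continue
        for alter in r.alters:
            if alter in idx:
                w[idx[r.ego], idx[alter]] = 1.0
                w[idx[alter], idx[r.ego]] = 1.0
    return WeightedNetwork(nodes, w, "binary")


def disparity_alpha(weight: float, node_strength: float, node_degree: int) -> float:
    """Disparity-filter significance of one edge seen from one endpoint.

    For a node of degree k and strength s, the probability that a uniform
    random split of s over k edges gives a normalised weight at least
    p = weight/s is alpha = (1 - p)^(k - 1).  Degree-1 nodes return 1 by
    convention (a spoke is never significant on its own).
    """
    if node_degree < 1:
        raise ValidationError("degree must be >= 1")
    if node_strength <= 0:
        raise ValidationError("strength must be positive")
    if weight < 0 or weight > node_strength * (1 + 1e-12):
        raise ValidationError("edge weight exceeds node strength")
    if node_degree == 1:
        return 1.0
    p = min(weight / node_strength, 1.0)
    return (1.0 - p) ** (node_degree - 1)


@dataclass
class BackboneResult:
    """Binary backbone extracted at the alpha matching a target density."""

    network: WeightedNetwork
    alpha_used: float
    achieved_density: float
    target_density: float


def edge_alphas(net: WeightedNetwork) -> np.ndarray:
    """min of the two endpoint alphas per dyad (upper-triangle order);
    edges with zero weight get alpha = 1 (never retained before any
    positive-weight edge)."""
    w = net.weights
    degree = (w > 0).sum(axis=1)
    strength = w.sum(axis=1)
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    out = np.ones(len(iu[0]))
    for k, (i, j) in enumerate(zip(*iu)):
        if w[i, j] <= 0:
            continue
        ai = disparity_alpha(w[i, j], strength[i], int(degree[i]))
        aj = disparity_alpha(w[i, j], strength[j], int(degree[j]))
        out[k] = min(ai, aj)
    return out


def backbone_at_density(
    net: WeightedNetwork, target_density: float
) -> BackboneResult:
    """Extract the disparity-filter backbone whose density best matches a
    target.

    The significance threshold is swept over the sorted distinct edge
    alphas; an edge is retained when its (min-endpoint) alpha is at most
    the chosen level.  Ties in |density - target| keep fewer edges.  All
    weights zero yields an empty backbone.
    """
    if not (0 < target_density <= 1):
        raise ValidationError("target density must be in (0, 1]")
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    n_dyads = len(iu[0])
    alphas = edge_alphas(net)
    positive = net.dyad_vector() > 0
    # candidate levels: each distinct alpha of a positive-weight edge,
    # plus "keep nothing"
    candidates = np.unique(alphas[positive]) if positive.any() else np.array([])
    best = (np.inf, np.inf, -1.0)  # (|density gap|, n_edges, level)
    for level in np.concatenate(([-1.0], candidates)):
        keep = positive & (alphas <= level)
        dens = keep.sum() / n_dyads if n_dyads else 0.0
        key = (abs(dens - target_density), int(keep.sum()), float(level))
        if (key[0], key[1]) < (best[0], best[1]):
            best = key
    level = best[2]
    keep = positive & (alphas <= level)
    w = np.zeros((n, n))
    w[iu[0][keep], iu[1][keep]] = 1.0
    w = w + w.T
    backbone = WeightedNetwork(net.nodes, w, "binary")
    return BackboneResult(
        network=backbone,
        alpha_used=float(level),
        achieved_density=backbone.density(),
        target_density=float(target_density),
    )


@dataclass
class MantelResult:
    rho: float
    p: float
    n_perm: int
    ci95: tuple[float, float]
    n_boot: int


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        raise UndefinedStatisticError("zero variance in a dyad weight vector")
    return float((rx * ry).sum() / denom)


def mantel(
    net_x: WeightedNetwork,
    net_y: WeightedNetwork,
    n_perm: int = 10000,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MantelResult:
    """Mantel test between two networks on the same ordered node set.

    rho is the Spearman correlation of the upper-triangle dyad vectors
    (ties mid-ranked).  The permutation null relabels X's nodes, applying
    one random permutation to rows and columns simultaneously; the
    two-sided p-value uses the +1 correction
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm).  The 95% CI is a
    percentile bootstrap over dyads resampled with replacement.
    """
    if net_x.nodes != net_y.nodes:
        raise ValidationError("networks are on different node sets")
    n = net_x.n_nodes
    if n < 3:
        raise ValidationError("Mantel test needs at least 3 nodes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    iu = np.triu_indices(n, k=1)
    x = net_x.weights[iu]
    y = net_y.weights[iu]
    rho = _spearman(x, y)

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = net_x.weights[np.ix_(perm, perm)][iu]
        r = _spearman_safe(xp, y)
        if r is not None and abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)

    boots = []
    m = len(x)
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        r = _spearman_safe(x[idx], y[idx])
        if r is not None:
            boots.append(r)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = rho
    return MantelResult(
        rho=rho, p=float(p), n_perm=n_perm, ci95=(float(lo), float(hi)), n_boot=n_boot
    )


def _spearman_safe(x: np.ndarray, y: np.ndarray) -> float | None:
    try:
        return _spearman(x, y)
    except UndefinedStatisticError:
        return None


def edge_overlap(
    net_x: WeightedNetwork, net_y: WeightedNetwork
) -> tuple[int, int]:
    """(edges present in both, edges in the reference net_y)."""
    if net_x.nodes != net_y.nodes:
        raise ValidationError("networks are on different node sets")
    for net in (net_x, net_y):
        if net.weight_kind != "binary":
            raise ValidationError("edge overlap requires binary networks")
    x = net_x.dyad_vector() > 0
    y = net_y.dyad_vector() > 0
    return int(np.sum(x & y)), int(np.sum(y))
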