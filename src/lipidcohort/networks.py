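"""Spearman correlation analysis and parameter-connectivity networks.

Per-group Spearman rank correlation matrices (metabolites + clinical
covariates) feed three data products: a two-triangle heatmap matrix (one
group per triangle), parameter-connectivity networks in which variables
are embedded by multidimensional scaling of the distance 1 - |rho| with
significance-thresholded correlation edges and Hotelling T² class
ellipses, and a biosynthetic pathway graph whose node sizes scale with
|ΔGM| and edge widths with |ΔP:S|.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortTable, ValidationError
from .indices import ActivityIndexResult
from .univariate import UnivariateResult

__all__ = [
    "CorrelationMatrixPair",
    "ConnectivityNetwork",
    "PathwayGraph",
    "spearman_pair",
    "spearman_exact",
    "correlation_distance",
    "mds_embed",
    "rigid_align",
    "hotelling_ellipse",
    "build_pcn",
    "build_pathway_graph",
    "heatmap_matrix",
]


# ---------------------------------------------------------------------------
# Correlation matrices
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrixPair:
    """Per-group Spearman rho and p matrices over a shared variable set."""

    variables: list[str]
    rho_group0: pd.DataFrame
    rho_group1: pd.DataFrame
    p_group0: pd.DataFrame
    p_group1: pd.DataFrame
    group_labels: tuple[str, str] = ("group0", "group1")


def _group_matrix(table: CohortTable, label: str, variables: list[str]) -> pd.DataFrame:
    mask = table.group_mask(label)
    frames = []
    for v in variables:
        if v in table.concentrations.columns:
            frames.append(table.concentrations.loc[mask, v])
        elif v in table.clinical.columns:
            frames.append(table.clinical.loc[mask, v])
        else:
            raise ValidationError(f"unknown variable {v!r}")
    return pd.concat(frames, axis=1)


def _spearman_matrices(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    if n < 4:
        raise ValidationError("need >= 4 subjects per group for correlations")
    import warnings

    with warnings.catch_warnings():
        # constant columns are masked explicitly below
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, pval = stats.spearmanr(arr)
    if p == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[np.nan, pval], [pval, np.nan]])
    rho = np.asarray(rho, dtype=float)
    pval = np.asarray(pval, dtype=float)
    const = np.nanstd(arr, axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    pval[const, :] = np.nan
    pval[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, np.nan)
    cols = list(X.columns)
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def spearman_pair(
    table: CohortTable, variables: list[str] | None = None
) -> CorrelationMatrixPair:
    """Per-group Spearman rho/p over metabolites + clinical covariates.

    Ties are handled by midranks; p-values use the t-distribution
    approximation.  Variables constant within a group get masked (NaN)
    rows/columns in that group's matrices.
    """
    if variables is None:
        variables = table.metabolites + list(table.clinical.columns)
    g0, g1 = table.group_order
    rho0, p0 = _spearman_matrices(_group_matrix(table, g0, variables))
    rho1, p1 = _spearman_matrices(_group_matrix(table, g1, variables))
    return CorrelationMatrixPair(
        variables=list(variables),
        rho_group0=rho0,
        rho_group1=rho1,
        p_group0=p0,
        p_group1=p1,
        group_labels=(g0, g1),
    )


def spearman_exact(x, y) -> tuple[float, float]:
    """Exact permutation Spearman test for small samples (n <= 8)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValidationError("need paired samples with n >= 3")
    if n > 8:
        raise ValidationError("exact permutation test limited to n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    obs = rho_of(rx, ry)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        if abs(rho_of(rx[list(perm)], ry)) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return obs, count / total


def correlation_distance(rho: pd.DataFrame) -> pd.DataFrame:
    """Distance d(i,j) = 1 - |rho(i,j)|, zero diagonal, masked rho -> 1."""
    d = 1.0 - rho.abs()
    d = d.fillna(1.0)
    vals = d.to_numpy()
    np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(vals, index=rho.index, columns=rho.columns)


def heatmap_matrix(pair: CorrelationMatrixPair, p_threshold: float = 0.05):
    """Two-triangle heatmap: group-0 rho strictly above the diagonal,
    group-1 strictly below; entries not significant at ``p_threshold`` are
    masked to 0."""
    p_count = len(pair.variables)
    out = np.zeros((p_count, p_count))
    r0 = pair.rho_group0.to_numpy()
    r1 = pair.rho_group1.to_numpy()
    s0 = pair.p_group0.to_numpy() < p_threshold
    s1 = pair.p_group1.to_numpy() < p_threshold
    iu = np.triu_indices(p_count, k=1)
    il = np.tril_indices(p_count, k=-1)
    out[iu] = np.where(s0[iu], r0[iu], 0.0)
    out[il] = np.where(s1[il], r1[il], 0.0)
    return pd.DataFrame(out, index=pair.variables, columns=pair.variables)


# ---------------------------------------------------------------------------
# MDS embedding
# ---------------------------------------------------------------------------


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(D: np.ndarray, coords: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    Dhat = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(D.shape[0], k=1)
    denom = (D[iu] ** 2).sum()
    if denom == 0:
        return 0.0
    return float(math.sqrt(((D[iu] - Dhat[iu]) ** 2).sum() / denom))


def mds_embed(
    d: pd.DataFrame | np.ndarray,
    dims: int = 2,
    method: str = "stress-majorization",
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Embed a distance matrix; returns (coordinates, Kruskal stress-1).

    ``stress-majorization`` runs seeded SMACOF initialized from the
    classical (Torgerson) solution; ``classical`` is the deterministic
    eigendecomposition alone, which reconstructs any dims-realizable
    Euclidean configuration exactly.
    """
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValidationError("distances must be symmetric, nonnegative, zero-diagonal")
    if dims >= n:
        raise ValidationError(f"dims must be < n points ({n})")
    init = _classical_mds(D, dims)
    if method == "classical":
        coords = init
    elif method == "stress-majorization":
        from sklearn.manifold import smacof

        coords, _ = smacof(
            D,
            n_components=dims,
            init=init,
            n_init=1,
            random_state=seed,
            normalized_stress=False,
        )
    else:
        raise ValidationError(f"unknown MDS method {method!r}")
    return coords, _stress1(D, coords)


def rigid_align(
    coords: np.ndarray, origin_index: int, quadrant_indices=None
) -> np.ndarray:
    """Distance-preserving alignment of a 2-D embedding.

    Translates the configuration so the node at ``origin_index`` sits at
    the origin, then rotates so the centroid of ``quadrant_indices`` lies
    in the lower-right quadrant (at -45 degrees).  Translation + rotation
    only, so all pairwise distances are unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    out = coords - coords[origin_index]
    if quadrant_indices is not None and len(quadrant_indices) and coords.shape[1] == 2:
        cx, cy = out[list(quadrant_indices)].mean(axis=0)
        if cx * cx + cy * cy > 1e-24:
            theta = -math.pi / 4.0 - math.atan2(cy, cx)
            c, s = math.cos(theta), math.sin(theta)
            out = out @ np.array([[c, s], [-s, c]])
    return out


# ---------------------------------------------------------------------------
# Hotelling T² class ellipses
# ---------------------------------------------------------------------------


def hotelling_ellipse(
    points, alpha: float = 0.05, prediction: bool = True
) -> tuple[np.ndarray, np.ndarray, float]:
    """Hotelling T² confidence ellipse for a point cloud.

    Returns ``(center, shape, radius)``: the boundary is the set
    ``(x - center)' shape^{-1} (x - center) = radius**2`` with
    ``shape`` the sample covariance and
    ``radius² = dims (k-1)/(k-dims) · F_{1-alpha}(dims, k-dims)``,
    multiplied by ``(k+1)/k`` when ``prediction`` is true (region for a
    new observation rather than the mean).
    """
    P = np.asarray(points, dtype=float)
    k, dims = P.shape
    if k <= dims + 1:
        raise ValidationError(f"need more than dims+1 = {dims + 1} points, got {k}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    center = P.mean(axis=0)
    shape = np.cov(P, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(shape) < dims:
        raise ValidationError("singular covariance; ellipse undefined")
    fq = stats.f.ppf(1.0 - alpha, dims, k - dims)
    r2 = dims * (k - 1) / (k - dims) * fq
    if prediction:
        r2 *= (k + 1) / k
    return center, shape, float(math.sqrt(r2))


# ---------------------------------------------------------------------------
# Parameter connectivity network
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityNetwork:
    """MDS-embedded variables with significance-thresholded edges."""

    group: str
    variables: list[str]
    roles: dict[str, str]
    coordinates: np.ndarray
    edges: list[tuple[str, str, float, float, int]]  # (i, j, rho, p, sign)
    class_ellipses: dict[str, tuple[np.ndarray, np.ndarray, float]]
    stress: float
    p_threshold: float
    alpha: float = 0.05

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v, xy in zip(self.variables, self.coordinates):
            g.add_node(
                v,
                role=self.roles[v],
                x=float(xy[0]),
                y=float(xy[1]),
            )
        for i, j, rho, p, sign in self.edges:
            g.add_edge(i, j, rho=float(rho), p=float(p), sign=int(sign))
        return g

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "role": [self.roles[v] for v in self.variables],
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
            }
        )

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["source", "target", "rho", "p", "sign"]
        )


def _node_role(table: CohortTable, v: str) -> str:
    if v in table.clinical.columns:
        return "clinical"
    ann = table.panel[v]
    return "metabolite<20C" if ann.carbons < 20 else "metabolite>=20C"


def build_pcn(
    table: CohortTable,
    group: str,
    p_threshold: float | None = None,
    dims: int = 2,
    method: str = "stress-majorization",
    seed: int = 0,
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> ConnectivityNetwork:
    """Build one group's parameter-connectivity network.

    Default edge thresholds follow the study convention: p < 0.05 for the
    reference (non-diseased) group and p < 0.01 for the disease group.
    Coordinates come from MDS of 1 - |rho|; when the variables include a
    glucose covariate it is placed at the origin with the SFA class
    centroid rotated into the lower-right quadrant (rigid motion only).
    Metabolite classes with at least dims + 2 embedded members receive
    Hotelling T² ellipses.
    """
    if group not in table.group_order:
        raise ValidationError(f"unknown group {group!r}")
    if p_threshold is None:
        p_threshold = 0.05 if group == table.group_order[0] else 0.01
    pair = spearman_pair(table, variables)
    is_ref = group == table.group_order[0]
    rho = pair.rho_group0 if is_ref else pair.rho_group1
    pmat = pair.p_group0 if is_ref else pair.p_group1
    dist = correlation_distance(rho)
    coords, stress = mds_embed(dist, dims=dims, method=method, seed=seed)

    names = list(dist.columns)
    glucose = [i for i, v in enumerate(names) if v.lower() == "glucose"]
    sfa = [
        i
        for i, v in enumerate(names)
        if v in table.panel and table.panel[v].chem_class == "SFA"
    ]
    if glucose and dims == 2:
        coords = rigid_align(coords, glucose[0], sfa or None)

    edges = []
    rv = rho.to_numpy()
    pv = pmat.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isfinite(pv[i, j]) and pv[i, j] < p_threshold:
                edges.append(
                    (
                        names[i],
                        names[j],
                        float(rv[i, j]),
                        float(pv[i, j]),
                        1 if rv[i, j] >= 0 else -1,
                    )
                )

    ellipses = {}
    for cls in table.panel.classes:
        member_idx = [
            i
            for i, v in enumerate(names)
            if v in table.panel and table.panel[v].chem_class == cls
        ]
        if len(member_idx) >= dims + 2:
            try:
                ellipses[cls] = hotelling_ellipse(coords[member_idx], alpha=alpha)
            except ValidationError:
                continue

    roles = {v: _node_role(table, v) for v in names}
    return ConnectivityNetwork(
        group=group,
        variables=names,
        roles=roles,
        coordinates=coords,
        edges=edges,
        class_ellipses=ellipses,
        stress=stress,
        p_threshold=p_threshold,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Pathway graph
# ---------------------------------------------------------------------------


@dataclass
class PathwayGraph:
    """Biosynthetic graph with effect-size-scaled nodes and edges."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def to_json(self) -> dict:
        return nx.node_link_data(self.graph, edges="links")


def _direction(delta: float, significant: bool) -> str:
    if not significant:
        return "not-significant"
    return "increased" if delta > 0 else "decreased"


def build_pathway_graph(
    univ: list[UnivariateResult],
    idx: list[ActivityIndexResult],
    table: CohortTable,
) -> PathwayGraph:
    """Assemble the pathway graph from univariate and ratio results.

    Node size is |ΔGM| (percent change in metabolite GM) with a border
    color encoding FDR significance and direction; edge width is |ΔP:S|
    (percent change in the product:substrate ratio GM) colored the same
    way.  Pathway edges lacking a ratio result are drawn gray with zero
    width and flagged.
    """
    by_name = {r.metabolite: r for r in univ}
    ratio_by_pair: dict[tuple[str, str], UnivariateResult] = {}
    for r in idx:
        for comp in r.components or [r]:
            if "/" in comp.name:
                prod, sub = comp.name.split("/", 1)
                ratio_by_pair[(sub, prod)] = comp.summary
    g = nx.DiGraph()
    for sub, prod, enzyme in table.panel.pathway_edges:
        for node in (sub, prod):
            if node not in g:
                res = by_name.get(node)
                if res is None:
                    g.add_node(node, size=0.0, direction="not-measured",
                               chem_class=table.panel[node].chem_class)
                else:
                    g.add_node(
                        node,
                        size=abs(res.delta_gm_pct),
                        direction=_direction(res.delta_gm_pct, res.fdr_significant),
                        chem_class=table.panel[node].chem_class,
                    )
        ratio = ratio_by_pair.get((sub, prod))
        if ratio is None:
            g.add_edge(sub, prod, enzyme=enzyme, width=0.0,
                       direction="not-measured", missing_ratio=True)
        else:
            g.add_edge(
                sub,
                prod,
                enzyme=enzyme,
                width=abs(ratio.delta_gm_pct),
                direction=_direction(ratio.delta_gm_pct, ratio.fdr_significant),
                missing_ratio=False,
            )
    return PathwayGraph(graph=g)
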