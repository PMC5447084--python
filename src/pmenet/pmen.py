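"""Phylogenetic molecular ecological networks (pMENs).

A pMEN is an undirected signed co-occurrence graph: nodes are taxa,
edges connect pairs whose pairwise similarity exceeds a cutoff chosen by
random matrix theory (RMT). The RMT criterion scans candidate cutoffs and
picks the point where the nearest-neighbour spacing distribution (NNSD)
of the unfolded eigenvalues of the thresholded similarity matrix
transitions from Gaussian-orthogonal-ensemble (Wigner) statistics — the
signature of a noise-dominated, strongly mixed spectrum — to Poisson
statistics, the signature of a modular system of quasi-independent
blocks. Modules are then detected by modularity maximization, and each
node is classified by its within-module degree z-score (Zi) and
among-module participation coefficient (Pi) into module hubs, network
hubs, connectors and peripherals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from pmenet.tables import FeatureTable

logger = logging.getLogger(__name__)

#: Zi / Pi cutoffs separating the four topological roles
ZI_CUTOFF = 2.5
PI_CUTOFF = 0.62


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    """Symmetric signed feature-feature association matrix in [-1, 1]."""

    values: pd.DataFrame
    method: str = "pearson"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1] or list(self.values.index) != list(self.values.columns):
            raise SimilarityError("similarity matrix must be square with matching ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise SimilarityError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise SimilarityError("similarity matrix must have unit diagonal")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


def correlation_matrix(
    table: FeatureTable,
    transform: str = "log_relative",
    pseudocount: float | None = None,
) -> SimilarityMatrix:
    """Pearson correlation across samples of (transformed) abundances.

    Default transform is ln(relative abundance + pseudocount) with a
    pseudocount of half the smallest nonzero relative abundance; pass
    ``transform="none"`` to correlate raw values. Zero-variance features
    cannot be correlated and are excluded (logged).
    """
    if table.n_samples < 4:
        raise SimilarityError("need at least 4 samples for a correlation matrix")
    x = table.relative_abundance().to_numpy()
    if transform == "log_relative":
        nz = x[x > 0]
        pc = pseudocount if pseudocount is not None else (nz.min() / 2 if nz.size else 1e-6)
        x = np.log(x + pc)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    sd = x.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
        logger.info("correlation_matrix: excluding %d zero-variance features", len(dropped))
    ids = [f for f, k in zip(table.feature_ids, keep) if k]
    r = np.corrcoef(x[keep])
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(pd.DataFrame(r, index=ids, columns=ids), method=f"pearson/{transform}")


# -- RMT threshold selection ----------------------------------------------

def unfold_and_nnsd(
    eigenvalues: np.ndarray,
    smoothing: float | None = None,
    degree: int = 3,
    min_eigs: int = 20,
) -> np.ndarray:
    """Unfold a spectrum and return nearest-neighbour spacings (mean 1).

    The empirical cumulative spectral function is fitted with a cubic
    smoothing spline N~(lambda); the unfolded levels e_i = N~(lambda_i)
    have unit mean density, so their consecutive differences are the NNSD
    sample. Degenerate eigenvalues (equal within 1e-8) are collapsed
    first — repeated eigenvalues of disconnected subgraphs would
    otherwise pile spurious zero spacings into the distribution.
    """
    eig = np.sort(np.asarray(eigenvalues, dtype=float))
    uniq = [eig[0]]
    for e in eig[1:]:
        if e - uniq[-1] > 1e-8:
            uniq.append(e)
    eig = np.array(uniq)
    n = eig.size
    if n < min_eigs:
        raise SimilarityError(f"need >= {min_eigs} distinct eigenvalues, got {n}")
    y = np.arange(1, n + 1) - 0.5
    s = smoothing if smoothing is not None else float(n)
    spline = UnivariateSpline(eig, y, k=degree, s=s)
    unfolded = spline(eig)
    spacings = np.clip(np.diff(unfolded), 0.0, None)
    mean = spacings.mean()
    if mean <= 0:
        raise SimilarityError("degenerate spectrum: zero mean spacing")
    return spacings / mean


def nnsd_pvalue(spacings: np.ndarray, dist: str) -> float:
    """Chi-square goodness of fit of the NNSD against Poisson or GOE.

    Bins are equiprobable under the tested law (Poisson: exp(-s); GOE
    Wigner surmise: (pi/2) s exp(-pi s^2 / 4)), with bin count capped so
    the expected count per bin stays >= 5.
    """
    n = spacings.size
    n_bins = int(max(3, min(25, n // 5)))
    q = np.arange(1, n_bins) / n_bins
    if dist == "poisson":
        edges = -np.log1p(-q)
    elif dist == "goe":
        edges = np.sqrt(-4.0 * np.log1p(-q) / np.pi)
    else:
        raise ValueError(f"unknown distribution {dist!r}")
    edges = np.concatenate([[0.0], edges, [np.inf]])
    observed, _ = np.histogram(spacings, bins=edges)
    expected = n / n_bins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=n_bins - 1))


@dataclass
class ThresholdScan:
    """Per-candidate-threshold NNSD statistics and the chosen cutoff."""

    scan: pd.DataFrame
    chosen_threshold: float | None
    alpha: float
    diagnostic: str = ""


def _thresholded_submatrix(values: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero |r| < threshold off-diagonal, restrict to non-isolated nodes."""
    a = values.copy()
    np.fill_diagonal(a, 0.0)
    a[np.abs(a) < threshold] = 0.0
    keep = (a != 0).any(axis=0)
    m = a[np.ix_(keep, keep)]
    np.fill_diagonal(m, 1.0)
    return m, keep


def rmt_threshold(
    sim: SimilarityMatrix,
    s_min: float = 0.30,
    s_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
    min_eigs: int = 20,
) -> ThresholdScan:
    """Scan similarity cutoffs for the GOE -> Poisson NNSD transition.

    For each candidate cutoff the similarity matrix is hard-thresholded,
    restricted to non-isolated features, and its eigenvalue spacings are
    tested against both laws. The chosen threshold is the smallest cutoff
    whose NNSD is consistent with Poisson (p > alpha) while inconsistent
    with the Wigner surmise (p <= alpha); if no cutoff qualifies the scan
    is returned with ``chosen_threshold`` unset and a diagnostic.
    """
    values = sim.values.to_numpy()
    candidates = np.round(np.arange(s_min, s_max + step / 2, step), 10)
    rows = []
    chosen = None
    for s in candidates:
        m, keep = _thresholded_submatrix(values, s)
        size = int(keep.sum())
        links = int((np.triu(m, 1) != 0).sum())
        row = {
            "threshold": float(s),
            "network_size": size,
            "total_links": links,
            "p_poisson": np.nan,
            "p_goe": np.nan,
        }
        if size >= min_eigs:
            eigs = np.linalg.eigvalsh(m)
            try:
                spacings = unfold_and_nnsd(eigs, min_eigs=min_eigs)
            except SimilarityError:
                rows.append(row)
                continue
            row["p_poisson"] = nnsd_pvalue(spacings, "poisson")
            row["p_goe"] = nnsd_pvalue(spacings, "goe")
            if chosen is None and row["p_poisson"] > alpha and row["p_goe"] <= alpha:
                chosen = float(s)
        rows.append(row)
    scan = pd.DataFrame(rows)
    diagnostic = "" if chosen is not None else (
        "no threshold reached the Poisson-consistent / Wigner-inconsistent regime"
    )
    if chosen is None:
        logger.warning("rmt_threshold: %s", diagnostic)
    return ThresholdScan(scan=scan, chosen_threshold=chosen, alpha=alpha, diagnostic=diagnostic)


# -- network construction and topology -------------------------------------

def build_network(sim: SimilarityMatrix, threshold: float, kind: str = "taxon") -> nx.Graph:
    """Graph with an edge wherever |r| >= threshold; isolated nodes removed.

    Edges carry the signed correlation as ``weight``, its magnitude as
    ``absweight`` (used for module detection) and ``sign``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ids = sim.feature_ids
    values = sim.values.to_numpy()
    g = nx.Graph()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    mask = np.abs(values[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        r = float(values[i, j])
        g.add_edge(ids[i], ids[j], weight=r, absweight=abs(r), sign="+" if r >= 0 else "-")
    if g.number_of_edges() == 0:
        logger.warning("build_network: no edge at threshold %.3f", threshold)
    for node in g.nodes:
        g.nodes[node]["kind"] = kind
    return g


def detect_modules(net: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Partition nodes into modules by greedy modularity maximization.

    Runs on |weight| so that strong negative associations bind as
    strongly as positive ones. Module labels are integers, assigned in
    order of each module's lexicographically smallest member for
    determinism. ``seed`` is accepted for interface stability; the greedy
    agglomeration itself is deterministic.
    """
    if net.number_of_nodes() == 0:
        return {}
    communities = nx.algorithms.community.greedy_modularity_communities(net, weight="absweight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    return {node: m for m, comm in enumerate(communities) for node in comm}


def modularity(net: nx.Graph, partition: dict[str, int], weighted: bool = False) -> float:
    """Newman-Girvan modularity Q of a partition.

    Q = sum_m (e_mm - a_m^2): the fraction of edges inside each module
    minus the expectation under a degree-preserving random rewiring.
    Computed on the unweighted graph by default; ``weighted=True`` uses
    |weight|.
    """
    missing = set(net.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition misses node(s): {sorted(missing)[:5]}")
    groups: dict[int, set] = {}
    for node, m in partition.items():
        if node in net:
            groups.setdefault(m, set()).add(node)
    if net.number_of_edges() == 0:
        return 0.0
    return float(
        nx.algorithms.community.modularity(
            net, list(groups.values()), weight="absweight" if weighted else None
        )
    )


def classify_role(zi: float, pi: float) -> str:
    """Topological role from the (Zi, Pi) plane.

    Zi > 2.5 marks hubs: module hubs at Pi < 0.62, network hubs at
    Pi > 0.62. Zi < 2.5 nodes are connectors at Pi > 0.62, peripherals
    otherwise. The quoted cutoffs are strict inequalities; boundary
    values fall into the peripheral-side category.
    """
    if zi > ZI_CUTOFF:
        return "network_hub" if pi > PI_CUTOFF else "module_hub"
    return "connector" if pi > PI_CUTOFF else "peripheral"


def node_roles(net: nx.Graph, partition: dict[str, int]) -> pd.DataFrame:
    """Zi / Pi connectivity statistics and topological role per node.

    Zi is the z-score of a node's within-module degree relative to the
    other members of its module (0 when the module has no degree spread);
    Pi = 1 - sum_m (k_im / k_i)^2 measures how evenly the node's links
    spread across modules. Roles: Zi > 2.5 marks hubs (module hubs at
    low Pi, network hubs at Pi > 0.62); Zi <= 2.5 nodes are connectors
    when Pi > 0.62 and peripherals otherwise.
    """
    missing = set(net.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition misses node(s): {sorted(missing)[:5]}")
    nodes = sorted(net.nodes)
    within = {}
    per_module_deg = {}
    for node in nodes:
        counts: dict[int, int] = {}
        for nbr in net.neighbors(node):
            counts[partition[nbr]] = counts.get(partition[nbr], 0) + 1
        per_module_deg[node] = counts
        within[node] = counts.get(partition[node], 0)
    rows = []
    for node in nodes:
        own = partition[node]
        members = [v for v in nodes if partition[v] == own]
        ks = np.array([within[v] for v in members], dtype=float)
        sd = ks.std()
        zi = 0.0 if sd == 0 or len(members) < 2 else (within[node] - ks.mean()) / sd
        k = net.degree(node)
        pi = 0.0
        if k > 0:
            pi = 1.0 - sum((km / k) ** 2 for km in per_module_deg[node].values())
        role = classify_role(zi, pi)
        rows.append({"node": node, "module": own, "zi": float(zi), "pi": float(pi), "role": role})
    return pd.DataFrame(rows).set_index("node")


@dataclass
class Pmen:
    """A thresholded co-occurrence network with modules and node roles."""

    graph: nx.Graph
    threshold: float
    partition: dict[str, int] = field(default_factory=dict)
    roles: pd.DataFrame | None = None
    scan: ThresholdScan | None = None

    def summary(self) -> dict:
        return summarize_pmen(self)


def summarize_pmen(pmen: Pmen) -> dict:
    """Topology summary: size, links, hubs, link signs, avgK = 2L/N, Q."""
    g = pmen.graph
    n, l = g.number_of_nodes(), g.number_of_edges()
    signs = [d.get("sign", "+") for _, _, d in g.edges(data=True)]
    pos = signs.count("+")
    n_hubs = 0
    if pmen.roles is not None and len(pmen.roles):
        n_hubs = int((pmen.roles["role"] == "module_hub").sum())
    q = modularity(g, pmen.partition) if pmen.partition and n else 0.0
    return {
        "threshold": pmen.threshold,
        "network_size": n,
        "total_links": l,
        "n_module_hubs": n_hubs,
        "pct_positive": 100.0 * pos / l if l else 0.0,
        "pct_negative": 100.0 * (l - pos) / l if l else 0.0,
        "avgK": 2.0 * l / n if n else 0.0,
        "modularity": q,
    }


def build_pmen(
    table: FeatureTable,
    threshold: float | None = None,
    transform: str = "log_relative",
    s_min: float = 0.30,
    s_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
) -> Pmen:
    """Full pMEN pipeline: similarity -> RMT threshold -> modules -> roles.

    ``threshold`` overrides the RMT scan when given. Raises if the scan
    finds no admissible threshold and none was supplied.
    """
    sim = correlation_matrix(table, transform=transform)
    scan = None
    if threshold is None:
        scan = rmt_threshold(sim, s_min=s_min, s_max=s_max, step=step, alpha=alpha)
        if scan.chosen_threshold is None:
            raise SimilarityError(f"RMT scan failed: {scan.diagnostic}")
        threshold = scan.chosen_threshold
    g = build_network(sim, threshold)
    partition = detect_modules(g, seed=seed)
    roles = node_roles(g, partition) if g.number_of_nodes() else pd.DataFrame()
    return Pmen(graph=g, threshold=threshold, partition=partition, roles=roles, scan=scan)
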