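"""Ensemble association networks with a compositionality-corrected null.

Associations between features (taxa-taxa, or taxa vs functional gene
categories) are scored by four measures — Pearson, Spearman, Bray-Curtis
dissimilarity and symmetrized Kullback-Leibler divergence — and each
measure is tested against a ReBoot null: feature profiles are permuted
across samples and every sample's composition is renormalized to unit
sum before rescoring, so that spurious associations induced purely by
the closed-sum constraint of relative abundances are present in the null
and cancel out. Permutation p-values are refined with a bootstrap
stability condition and combined across the four (strongly dependent)
measures with Brown's method; edges survive only with support from at
least two measures, a correlation coefficient above 0.8, and a combined
p below 0.05 (optionally Benjamini-Hochberg adjusted across pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pmenet.pmen import detect_modules, modularity
from pmenet.tables import FeatureTable

logger = logging.getLogger(__name__)

MEASURES = ("pearson", "spearman", "bray_curtis", "kld_sym")
CORRELATION_MEASURES = ("pearson", "spearman")


# -- vectorized measures ---------------------------------------------------

def _close(x: np.ndarray) -> np.ndarray:
    """Renormalize columns (samples) to unit sum; all-zero columns stay."""
    totals = x.sum(axis=0, keepdims=True)
    return x / np.where(totals > 0, totals, 1.0)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1, keepdims=True))
    bsd = np.sqrt((bz**2).sum(axis=1, keepdims=True))
    asd[asd == 0] = np.nan
    bsd[bsd == 0] = np.nan
    r = (az / asd) @ (bz / bsd).T
    return np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def _unit_profiles(x: np.ndarray) -> np.ndarray:
    """Normalize each feature's profile across samples to unit sum."""
    totals = x.sum(axis=1, keepdims=True)
    return x / np.where(totals > 0, totals, 1.0)


def _bray_curtis(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # compare unit-sum profiles so cross-table scale differences
    # (taxon shares vs category shares) do not swamp the shape signal
    a, b = _unit_profiles(a), _unit_profiles(b)
    num = np.abs(a[:, None, :] - b[None, :, :]).sum(axis=2)
    den = (a[:, None, :] + b[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    return np.nan_to_num(d, nan=0.0)


def _kld_sym(a: np.ndarray, b: np.ndarray, pseudocount: float) -> np.ndarray:
    """Symmetrized KL between per-feature profiles normalized to sum 1."""
    p = (a + pseudocount) / (a + pseudocount).sum(axis=1, keepdims=True)
    q = (b + pseudocount) / (b + pseudocount).sum(axis=1, keepdims=True)
    lp, lq = np.log(p), np.log(q)
    ap = (p * lp).sum(axis=1)
    bq = (q * lq).sum(axis=1)
    return ap[:, None] + bq[None, :] - p @ lq.T - lp @ q.T


def measure_matrices(
    a: np.ndarray, b: np.ndarray, pseudocount: float
) -> dict[str, np.ndarray]:
    """All four measure matrices between rows of ``a`` and rows of ``b``."""
    return {
        "pearson": _rowwise_pearson(a, b),
        "spearman": _rowwise_pearson(_rank_rows(a), _rank_rows(b)),
        "bray_curtis": _bray_curtis(a, b),
        "kld_sym": _kld_sym(a, b, pseudocount),
    }


def pairwise_measures(
    tableA: FeatureTable,
    tableB: FeatureTable | None = None,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Observed scores of all four measures for every feature pair.

    With one table, all within-table pairs are scored; with two tables
    (e.g. taxa and gene categories) every cross pair is scored. Tables
    are closed to relative abundance per sample first. Requires at least
    5 shared samples — the measures are unstable below that.
    """
    if tableB is not None:
        shared = [s for s in tableA.sample_ids if s in set(tableB.sample_ids)]
        if len(shared) < 5:
            raise ValueError(f"only {len(shared)} shared samples; need >= 5")
        tableA = tableA.select_samples(shared)
        tableB = tableB.select_samples(shared)
    elif tableA.n_samples < 5:
        raise ValueError(f"only {tableA.n_samples} samples; need >= 5")
    a = _close(tableA.to_numpy())
    ids_a = tableA.feature_ids
    if tableB is None:
        b, ids_b = a, ids_a
        pairs = list(combinations(range(len(ids_a)), 2))
    else:
        b = _close(tableB.to_numpy())
        ids_b = tableB.feature_ids
        pairs = [(i, j) for i in range(len(ids_a)) for j in range(len(ids_b))]
    mats = measure_matrices(a, b, pseudocount)
    rows = [
        {"feature_a": ids_a[i], "feature_b": ids_b[j]}
        | {m: float(mats[m][i, j]) for m in MEASURES}
        for i, j in pairs
    ]
    return pd.DataFrame(rows).set_index(["feature_a", "feature_b"])


# -- ReBoot null and bootstrap --------------------------------------------

def _permute_rows(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = x[i, rng.permutation(x.shape[1])]
    return out


def reboot_null(
    tableA: FeatureTable,
    pair: tuple[str, str],
    measure: str,
    tableB: FeatureTable | None = None,
    n_perm: int = 100,
    seed: int = 0,
    pseudocount: float = 1e-6,
) -> np.ndarray:
    """ReBoot null distribution of one measure for one feature pair.

    Each permutation shuffles the two features' profiles across samples
    independently, renormalizes every sample of the affected table(s) to
    unit sum (keeping the compositional constraint in the null), and
    rescores the pair.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    fa, fb = pair
    a = tableA.to_numpy().astype(float)
    ia = tableA.feature_ids.index(fa)
    if tableB is None:
        b, ib = a, tableA.feature_ids.index(fb)
    else:
        b = tableB.to_numpy().astype(float)
        ib = tableB.feature_ids.index(fb)
    out = np.empty(n_perm)
    for t in range(n_perm):
        ap = a.copy()
        ap[ia] = a[ia, rng.permutation(a.shape[1])]
        if tableB is None:
            ap[ib] = a[ib, rng.permutation(a.shape[1])]
            bp = ap
        else:
            bp = b.copy()
            bp[ib] = b[ib, rng.permutation(b.shape[1])]
            bp = _close(bp)
        ap = _close(ap)
        if tableB is None:
            bp = ap
        m = measure_matrices(ap[[ia]], bp[[ib]], pseudocount)[measure]
        out[t] = m[0, 0]
    return out


def bootstrap_dist(
    tableA: FeatureTable,
    pair: tuple[str, str],
    measure: str,
    tableB: FeatureTable | None = None,
    n_boot: int = 100,
    seed: int = 0,
    pseudocount: float = 1e-6,
) -> np.ndarray:
    """Bootstrap distribution of one measure: samples drawn with replacement."""
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 12]))
    fa, fb = pair
    a = _close(tableA.to_numpy().astype(float))
    ia = tableA.feature_ids.index(fa)
    if tableB is None:
        b, ib = a, tableA.feature_ids.index(fb)
    else:
        b = _close(tableB.to_numpy().astype(float))
        ib = tableB.feature_ids.index(fb)
    n = a.shape[1]
    out = np.empty(n_boot)
    for t in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = measure_matrices(a[[ia]][:, idx], b[[ib]][:, idx], pseudocount)[measure]
        out[t] = m[0, 0]
    return out


def measure_pvalue(
    observed: float,
    null_sample: np.ndarray,
    boot_sample: np.ndarray | None = None,
) -> float:
    """Two-sided permutation p for one measure score.

    The p-value comes from the z-score of the observed score against the
    null mean and sd, floored at 1/(n_perm + 1). When a bootstrap sample
    is supplied, the edge must also be *stable*: if the bootstrap 95%
    percentile interval covers the null mean the pair is declared
    non-significant (p = 1).
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    floor = 1.0 / (null_sample.size + 1)
    mu, sd = null_sample.mean(), null_sample.std()
    if sd == 0:
        p = 1.0 if observed == mu else floor
    else:
        p = float(2.0 * stats.norm.sf(abs(observed - mu) / sd))
        p = min(max(p, floor), 1.0)
    if boot_sample is not None and len(boot_sample):
        lo, hi = np.percentile(boot_sample, [2.5, 97.5])
        if lo <= mu <= hi:
            return 1.0
    return p


# -- Brown's method --------------------------------------------------------

def brown_combine(p_values, cov: np.ndarray | None = None, floor: float = 1e-15) -> float:
    """Combine dependent p-values with Brown's scaled chi-square.

    X = -2 sum ln p ~ c * chi2(df) with E[X] = 2k and Var[X] = 4k +
    2 sum_{i<j} cov(-2 ln p_i, -2 ln p_j); c = Var/(2E), df = 2E^2/Var.
    With zero covariance this reduces exactly to Fisher's method.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1 or p.size > 4:
        raise ValueError("expected 1-4 p-values")
    if (p <= 0).any():
        logger.warning("brown_combine: clamping nonpositive p-value(s) to %g", floor)
        p = np.clip(p, floor, 1.0)
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    k = p.size
    x = float(-2.0 * np.log(p).sum())
    expected = 2.0 * k
    var = 4.0 * k
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        iu = np.triu_indices(k, 1)
        var += 2.0 * float(cov[iu].sum())
    var = max(var, 1e-12)
    c = var / (2.0 * expected)
    df = 2.0 * expected**2 / var
    return float(stats.chi2.sf(x / c, df=df))


def _null_log_p_cov(null_block: np.ndarray) -> np.ndarray:
    """Covariance of -2 ln p across the shared permutation stream.

    ``null_block`` is (n_perm, n_measures): each permutation's scores for
    one pair under all measures. Each null score is converted to its own
    z-based p against the null distribution, and the covariance of
    -2 ln p across permutations estimates the dependence the measures
    inherit from being computed on identical data.
    """
    n, k = null_block.shape
    mu = null_block.mean(axis=0)
    sd = null_block.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    pz = 2.0 * stats.norm.sf(np.abs(null_block - mu) / sd)
    pz = np.clip(pz, 1.0 / (n + 1), 1.0)
    return np.cov(-2.0 * np.log(pz), rowvar=False)


# -- the full ensemble pipeline -------------------------------------------

@dataclass
class EnsembleResult:
    """Edge table plus the retained-edge graph and its topology summary."""

    edges: pd.DataFrame
    graph: nx.Graph
    summary: dict


def score_pairs(
    tableA: FeatureTable,
    tableB: FeatureTable | None = None,
    n_perm: int = 100,
    n_boot: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Score every pair with all measures, ReBoot p-values and Brown p.

    Permutations and bootstraps are shared across pairs (one permuted
    table per iteration) which is what lets the Brown covariance of
    -2 ln p be estimated from the same stream.
    """
    if n_perm < 20 or n_boot < 20:
        raise ValueError("n_perm and n_boot must be >= 20")
    cross = tableB is not None
    if cross:
        shared = [s for s in tableA.sample_ids if s in set(tableB.sample_ids)]
        if len(shared) < 5:
            raise ValueError(f"only {len(shared)} shared samples; need >= 5")
        tableA = tableA.select_samples(shared)
        tableB = tableB.select_samples(shared)
    a_raw = tableA.to_numpy().astype(float)
    b_raw = tableB.to_numpy().astype(float) if cross else a_raw
    a = _close(a_raw)
    b = _close(b_raw) if cross else a
    ids_a, ids_b = tableA.feature_ids, (tableB.feature_ids if cross else tableA.feature_ids)
    if cross:
        pairs = [(i, j) for i in range(len(ids_a)) for j in range(len(ids_b))]
    else:
        pairs = list(combinations(range(len(ids_a)), 2))
    observed = measure_matrices(a, b, pseudocount)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    null = {m: np.empty((n_perm, len(pairs))) for m in MEASURES}
    for t in range(n_perm):
        ap = _close(_permute_rows(a_raw, rng))
        bp = _close(_permute_rows(b_raw, rng)) if cross else ap
        mats = measure_matrices(ap, bp, pseudocount)
        for m in MEASURES:
            null[m][t] = [mats[m][i, j] for i, j in pairs]

    rng_b = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    boot = {m: np.empty((n_boot, len(pairs))) for m in MEASURES}
    n_samples = a.shape[1]
    for t in range(n_boot):
        idx = rng_b.integers(0, n_samples, size=n_samples)
        mats = measure_matrices(a[:, idx], b[:, idx], pseudocount)
        for m in MEASURES:
            boot[m][t] = [mats[m][i, j] for i, j in pairs]

    rows = []
    for c, (i, j) in enumerate(pairs):
        rec: dict = {"feature_a": ids_a[i], "feature_b": ids_b[j]}
        p_vec = []
        for m in MEASURES:
            score = float(observed[m][i, j])
            p = measure_pvalue(score, null[m][:, c], boot[m][:, c])
            rec[m] = score
            rec[f"p_{m}"] = p
            p_vec.append(p)
        block = np.column_stack([null[m][:, c] for m in MEASURES])
        rec["combined_p"] = brown_combine(p_vec, cov=_null_log_p_cov(block))
        rec["support"] = int(sum(p < alpha for p in p_vec))
        dominant = max(CORRELATION_MEASURES, key=lambda m: abs(rec[m]))
        rec["sign"] = "+" if rec[dominant] >= 0 else "-"
        rec["max_abs_corr"] = max(abs(rec[m]) for m in CORRELATION_MEASURES)
        rows.append(rec)
    return pd.DataFrame(rows).set_index(["feature_a", "feature_b"])


def filter_edges(
    edges: pd.DataFrame,
    min_support: int = 2,
    min_coeff: float = 0.8,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Apply the robustness filters and return the edge table with flags.

    Retained edges need (i) support from at least ``min_support``
    measures, (ii) a correlation coefficient (Pearson or Spearman)
    exceeding ``min_coeff`` in magnitude — the dissimilarity measures
    contribute to support but carry no coefficient cutoff — and (iii)
    combined p below ``alpha``, Benjamini-Hochberg adjusted across pairs
    when ``fdr=True``. The default is the raw combined p: with four
    dependent measures the Brown p is floor-limited by the permutation
    count, and the coefficient filter already suppresses false edges.
    """
    out = edges.copy()
    if len(out) == 0:
        out["adjusted_p"] = pd.Series(dtype=float)
        out["retained"] = pd.Series(dtype=bool)
        return out
    if fdr:
        out["adjusted_p"] = multipletests(out["combined_p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["adjusted_p"] = out["combined_p"]
    out["retained"] = (
        (out["support"] >= min_support)
        & (out["max_abs_corr"] > min_coeff)
        & (out["adjusted_p"] < alpha)
    )
    return out


def build_bipartite(
    edges: pd.DataFrame,
    kind_a: str = "taxon",
    kind_b: str = "function",
    seed: int = 0,
) -> EnsembleResult:
    """Graph of retained edges with its topology summary.

    Note the degree convention: ``average_degree`` here is E/N (edges per
    node), not the 2L/N connectivity used for pMENs.
    """
    kept = edges[edges["retained"]] if "retained" in edges else edges
    g = nx.Graph()
    for (fa, fb), row in kept.iterrows():
        dominant = max(CORRELATION_MEASURES, key=lambda m: abs(row[m]))
        g.add_node(fa, kind=kind_a)
        g.add_node(fb, kind=kind_b)
        g.add_edge(
            fa,
            fb,
            weight=float(row[dominant]),
            absweight=abs(float(row[dominant])),
            sign=str(row["sign"]),
            support=int(row["support"]),
            combined_p=float(row["combined_p"]),
        )
    n, e = g.number_of_nodes(), g.number_of_edges()
    partition = detect_modules(g, seed=seed)
    q = modularity(g, partition) if n else 0.0
    summary = {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": e / n if n else 0.0,
        "modularity": q,
    }
    return EnsembleResult(edges=edges, graph=g, summary=summary)


def ensemble_network(
    tableA: FeatureTable,
    tableB: FeatureTable | None = None,
    n_perm: int = 100,
    n_boot: int = 100,
    min_support: int = 2,
    min_coeff: float = 0.8,
    alpha: float = 0.05,
    fdr: bool = False,
    seed: int = 0,
    pseudocount: float = 1e-6,
    kind_a: str = "taxon",
    kind_b: str = "function",
) -> EnsembleResult:
    """End-to-end ensemble inference: score, filter, build the network."""
    edges = score_pairs(
        tableA, tableB, n_perm=n_perm, n_boot=n_boot, seed=seed, alpha=alpha,
        pseudocount=pseudocount,
    )
    edges = filter_edges(edges, min_support=min_support, min_coeff=min_coeff, alpha=alpha, fdr=fdr)
    return build_bipartite(edges, kind_a=kind_a, kind_b=kind_b if tableB is not None else kind_a, seed=seed)
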