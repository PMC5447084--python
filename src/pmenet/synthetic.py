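"""Synthetic OTU-count and functional-gene-array tables with planted structure.

The generator emulates a mesocosm study design of 3 soil types x 4 depth
layers x 2 growth stages x 2 replicates = 48 samples. Taxon abundances
follow a log-normal latent field with block correlation (planted
co-occurrence modules); counts are multinomial draws per sample, which
induces the compositional closure that the downstream ReBoot null is
designed to correct. Functional gene categories are either coupled to a
taxon's latent abundance (planted taxa-function associations) or pure
scanner noise. Every planted fact is returned as a :class:`PlantedTruth`
so downstream recovery is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from pmenet.tables import FeatureTable

LAYER_LABELS = "ABCD"

#: functional gene categories typical of a functional gene array
GENE_CATEGORIES = (
    "Carbon_cycling",
    "Metal_resistance",
    "Organic_remediation",
    "Nitrogen_cycling",
    "Sulfur_cycling",
    "Phosphorus_cycling",
    "Energy_process",
    "Antibiotic_resistance",
    "Stress_response",
    "Methane_cycling",
    "Virulence",
    "Bacteriophage",
)


class CovarianceError(RuntimeError):
    """Planted covariance could not be made positive semi-definite."""


@dataclass
class SyntheticConfig:
    """Study design and planted-structure parameters.

    The design defaults reproduce the 48-sample layout (3 soil types, 4
    depth layers, 2 growth stages, 2 mesocosm replicates); the default
    sequencing depth matches the rarefaction depth used for the bacterial
    libraries (42364 reads per sample).
    """

    n_soil_types: int = 3
    n_layers: int = 4
    n_stages: int = 2
    n_replicates: int = 2
    n_taxa: int = 40
    n_background_taxa: int = 0  # uncorrelated taxa outside every module
    n_gene_categories: int = 12
    n_modules: int = 4
    within_module_rho: float = 0.8
    cross_module_rho: float = 0.0
    means_sd: float = 1.0  # spread of per-taxon log-abundance means
    coupling_strength: float = 0.9
    n_coupled_categories: int | None = None  # default: half the categories
    sequencing_depth: int = 42364
    depth_cv: float = 0.0  # per-sample depth variability before rarefaction
    background_mean: float = 1000.0
    background_sd: float = 100.0
    signal_gain: float = 200.0  # sd of a coupled category's signal
    layer_effect: float = 0.0  # per-layer latent-mean shift (depth gradient)
    layer_effect_taxa: int = 0  # how many taxa respond to depth
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_soil_types", "n_layers", "n_stages", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.within_module_rho < 1):
            raise ValueError("within_module_rho must be in [0, 1)")
        if not (0 <= self.coupling_strength < 1):
            raise ValueError("coupling_strength must be in [0, 1)")
        if self.within_module_rho <= self.cross_module_rho and self.within_module_rho > 0:
            raise ValueError("within_module_rho must exceed cross_module_rho")
        if not (0 <= self.n_background_taxa <= self.n_taxa):
            raise ValueError("n_background_taxa must be in [0, n_taxa]")
        if self.n_modules < 1 or self.n_taxa - self.n_background_taxa < self.n_modules:
            raise ValueError("need n_taxa - n_background_taxa >= n_modules >= 1")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_soil_types * self.n_layers * self.n_stages * self.n_replicates

    def coupled_categories(self) -> int:
        if self.n_coupled_categories is None:
            return self.n_gene_categories // 2
        return min(self.n_coupled_categories, self.n_gene_categories)


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every synthetic table."""

    module_of: dict[str, int]
    true_pairs: set[frozenset]
    latent_means: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "true_pairs": sorted(sorted(p) for p in self.true_pairs),
            "latent_means": self.latent_means,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            module_of=payload["module_of"],
            true_pairs={frozenset(p) for p in payload["true_pairs"]},
            latent_means=payload.get("latent_means", {}),
        )


def taxon_ids(config: SyntheticConfig) -> list[str]:
    width = len(str(config.n_taxa))
    return [f"OTU{i + 1:0{width}d}" for i in range(config.n_taxa)]


def gene_category_ids(config: SyntheticConfig) -> list[str]:
    names = list(GENE_CATEGORIES[: config.n_gene_categories])
    for k in range(len(names), config.n_gene_categories):
        names.append(f"Category_{k + 1}")
    return names


def sample_design(config: SyntheticConfig) -> pd.DataFrame:
    """Sample metadata table for the full-factorial mesocosm design."""
    rows = []
    for s in range(config.n_soil_types):
        for l in range(config.n_layers):
            layer = LAYER_LABELS[l] if l < len(LAYER_LABELS) else f"L{l + 1}"
            for g in range(config.n_stages):
                for r in range(config.n_replicates):
                    sid = f"S{s + 1}-{layer}-t{g + 1}-r{r + 1}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "soil_type": f"S{s + 1}",
                            "layer": layer,
                            "stage": f"t{g + 1}",
                            "replicate": f"r{r + 1}",
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _block_correlation(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Block-structured correlation matrix and the module label per taxon.

    The first n_taxa - n_background_taxa taxa are assigned to modules in
    contiguous, near-equal blocks; background taxa are mutually
    uncorrelated and each carries its own singleton module label. If the
    requested correlation pattern is not positive semi-definite, all
    off-diagonal entries are shrunk by 0.95 repeatedly until it is.
    """
    n_module_taxa = config.n_taxa - config.n_background_taxa
    labels = np.array_split(np.arange(n_module_taxa), config.n_modules)
    module = np.empty(config.n_taxa, dtype=int)
    for m, idx in enumerate(labels):
        module[idx] = m
    module[n_module_taxa:] = config.n_modules + np.arange(config.n_background_taxa)
    same = module[:, None] == module[None, :]
    background = module >= config.n_modules
    cross = np.where(
        background[:, None] | background[None, :], 0.0, config.cross_module_rho
    )
    corr = np.where(same, config.within_module_rho, cross).astype(float)
    np.fill_diagonal(corr, 1.0)
    for _ in range(200):
        if np.linalg.eigvalsh(corr).min() >= -1e-10:
            return corr, module
        off = ~np.eye(config.n_taxa, dtype=bool)
        corr[off] *= 0.95
    raise CovarianceError("correlation matrix not PSD after shrinkage")


def generate_latent(config: SyntheticConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Draw the latent log-abundance field (taxa x samples).

    The field is multivariate normal with the planted block correlation;
    per-taxon means give the community a log-normal abundance spread, and
    an optional depth gradient shifts a subset of taxa by
    ``layer_effect`` per layer step (so a "surface vs depth enriched"
    contrast exists when requested).
    """
    corr, module = _block_correlation(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    ids = taxon_ids(config)
    means = rng.normal(0.0, config.means_sd, size=config.n_taxa)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(config.n_taxa))
    z = chol @ rng.standard_normal((config.n_taxa, config.n_samples))
    latent = z + means[:, None]
    design = sample_design(config)
    if config.layer_effect != 0.0 and config.layer_effect_taxa > 0:
        layer_rank = np.array(
            [LAYER_LABELS.index(l) if l in LAYER_LABELS else 0 for l in design["layer"]]
        )
        k = min(config.layer_effect_taxa, config.n_taxa)
        latent[:k, :] += config.layer_effect * layer_rank[None, :]
    df = pd.DataFrame(latent, index=ids, columns=design.index)
    truth = PlantedTruth(
        module_of={ids[i]: int(module[i]) for i in range(config.n_taxa)},
        true_pairs={
            frozenset((ids[i], ids[j]))
            for i in range(config.n_taxa)
            for j in range(i + 1, config.n_taxa)
            if module[i] == module[j] and config.within_module_rho > 0
        },
        latent_means={ids[i]: float(means[i]) for i in range(config.n_taxa)},
    )
    return df, truth


def sample_counts(
    latent: pd.DataFrame,
    depth: int,
    seed: int = 0,
    depth_cv: float = 0.0,
    sample_metadata: pd.DataFrame | None = None,
) -> FeatureTable:
    """Multinomial read counts per sample from the latent field.

    Each sample column is a single multinomial draw whose probabilities
    are proportional to exp(latent); the closed column sum (== depth, up
    to optional log-normal depth variability ``depth_cv``) makes the
    counts compositional by construction.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not np.isfinite(latent.to_numpy()).all():
        raise ValueError("latent matrix must be finite")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    z = latent.to_numpy()
    probs = np.exp(z - z.max(axis=0, keepdims=True))
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.empty_like(z, dtype=np.int64)
    for j in range(z.shape[1]):
        d = depth
        if depth_cv > 0:
            d = max(1, int(round(depth * rng.lognormal(0.0, depth_cv))))
        counts[:, j] = rng.multinomial(d, probs[:, j])
    df = pd.DataFrame(counts, index=latent.index, columns=latent.columns)
    return FeatureTable(df, sample_metadata=sample_metadata)


def generate_geochip(
    latent: pd.DataFrame,
    truth: PlantedTruth,
    config: SyntheticConfig,
) -> tuple[FeatureTable, PlantedTruth]:
    """Gene-category signal intensities coupled to taxon abundances.

    The first ``coupled_categories()`` categories track one taxon each:
    signal = background_mean + signal_gain * (w*z + sqrt(1-w^2)*noise)
    with w = coupling_strength, so the planted category-taxon correlation
    is exactly w before clipping. Remaining categories are pure scanner
    noise at (background_mean, background_sd). Negative intensities are
    clipped at zero (scanners report non-negative signal). The returned
    truth is ``truth`` extended with the coupled pairs.
    """
    if config.background_sd <= 0:
        raise ValueError("background_sd must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    cats = gene_category_ids(config)
    n_coupled = config.coupled_categories()
    # couple categories to module taxa only (background taxa are pure noise)
    taxa = list(latent.index)[: config.n_taxa - config.n_background_taxa]
    n_samples = latent.shape[1]
    w = config.coupling_strength
    spacing = max(1, len(taxa) // max(1, n_coupled))
    signals = np.empty((len(cats), n_samples))
    coupled_pairs = set()
    for g, cat in enumerate(cats):
        if g < n_coupled and w > 0:
            taxon = taxa[(g * spacing) % len(taxa)]
            # couple to the taxon's *closed* log abundance — the scale on
            # which the association is observable in compositional data
            lat = latent.to_numpy()
            logrel = latent.loc[taxon].to_numpy() - logsumexp(lat, axis=0)
            z = (logrel - logrel.mean()) / (logrel.std() or 1.0)
            eps = rng.standard_normal(n_samples)
            signals[g] = config.background_mean + config.signal_gain * (
                w * z + np.sqrt(1.0 - w**2) * eps
            )
            coupled_pairs.add(frozenset((cat, taxon)))
        else:
            signals[g] = rng.normal(config.background_mean, config.background_sd, n_samples)
    signals = np.clip(signals, 0.0, None)
    df = pd.DataFrame(signals, index=cats, columns=latent.columns)
    table = FeatureTable(df, feature_annotation={c: c for c in cats})
    new_truth = PlantedTruth(
        module_of=dict(truth.module_of),
        true_pairs=set(truth.true_pairs) | coupled_pairs,
        latent_means=dict(truth.latent_means),
    )
    return table, new_truth


def generate_study(config: SyntheticConfig) -> dict:
    """One full synthetic study: counts, array signals, metadata, truth."""
    latent, truth = generate_latent(config)
    design = sample_design(config)
    counts = sample_counts(
        latent,
        config.sequencing_depth,
        seed=config.seed,
        depth_cv=config.depth_cv,
        sample_metadata=design,
    )
    geochip, truth = generate_geochip(latent, truth, config)
    geochip.sample_metadata = design
    return {
        "latent": latent,
        "counts": counts,
        "geochip": geochip,
        "metadata": design,
        "truth": truth,
    }
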