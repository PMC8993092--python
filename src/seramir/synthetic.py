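"""Synthetic serum small-RNA data emulating a patients-vs-controls study design.

Counts are drawn from a negative binomial with mean ``libsize_s * p_g`` and
dispersion phi (variance = mu + phi * mu^2), where the relative abundances
``p_g`` sum to one per condition. A configurable fraction of miRNAs is truly
differential with log2 fold changes of +/- a stated magnitude; library sizes
vary uniformly per sample so normalization is never trivial. The default
design is eight patients versus twenty-two matched healthy controls.

One integer seed governs every draw through a single generator stream. Draw
order: (1) baseline log relative abundances, (2) optional per-miRNA
dispersions, (3) choice of truly differential miRNAs, (4) their fold-change
signs, (5) per-sample library sizes (patients first, then controls),
(6) the count matrix column by column (patients first).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import CountMatrix, CONTROL, PATIENT

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_null",
    "simulate_edge_lists",
    "simulate_annotations",
    "simulate_ontology",
    "simulate_biotypes",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the count simulator.

    dispersion is the NB phi in variance = mu + phi*mu^2; a value of 0 gives
    Poisson counts. ``tagwise_dispersion_sd`` > 0 draws per-miRNA dispersions
    from a log-normal centered on ``dispersion``.
    """

    n_mirnas: int = 200
    n_patients: int = 8
    n_controls: int = 22
    frac_de: float = 0.0
    lfc_magnitude: float = 2.0
    dispersion: float = 0.2
    libsize_range: tuple[int, int] = (1_000_000, 5_000_000)
    baseline_logmean_range: tuple[float, float] = (-2.5, 2.5)
    tagwise_dispersion_sd: float = 0.0
    disease: str = "disease"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0 or self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("n_mirnas, n_patients and n_controls must be positive")
        if self.n_patients + self.n_controls < 4:
            raise ValueError("at least 4 samples are required in total")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise ValueError("lfc_magnitude must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ValueError("libsize_range must satisfy 0 < low <= high")
        lo_b, hi_b = self.baseline_logmean_range
        if hi_b < lo_b:
            raise ValueError("baseline_logmean_range low must not exceed high")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_mirnas))


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    sample_sheet: pd.DataFrame  # sample_id, group, disease
    truth: dict[str, float] = field(default_factory=dict)  # mirna -> signed log2FC

    @property
    def truth_ids(self) -> set[str]:
        return set(self.truth)

    @property
    def labels(self) -> pd.Series:
        return self.sample_sheet.set_index("sample_id")["group"]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])  # success probability of numpy's NB parameterization
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full dataset (counts, sample sheet, ground-truth DE set)."""
    rng = np.random.default_rng(config.seed)
    G = config.n_mirnas

    log_base = rng.uniform(*config.baseline_logmean_range, size=G)
    if config.tagwise_dispersion_sd > 0:
        phi = config.dispersion * rng.lognormal(
            -0.5 * config.tagwise_dispersion_sd**2, config.tagwise_dispersion_sd, size=G
        )
    else:
        phi = np.full(G, float(config.dispersion))

    mirnas = np.array([f"mir-{i:05d}" for i in range(G)])
    n_de = config.n_de
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    lfc = np.zeros(G)
    lfc[de_idx] = signs * config.lfc_magnitude

    n_samples = config.n_patients + config.n_controls
    lo, hi = config.libsize_range
    libsizes = rng.integers(lo, hi + 1, size=n_samples)

    base = np.exp(log_base)
    p_control = base / base.sum()
    shifted = base * 2.0**lfc
    p_patient = shifted / shifted.sum()

    sample_ids = [f"patient_{i + 1:02d}" for i in range(config.n_patients)] + [
        f"control_{i + 1:02d}" for i in range(config.n_controls)
    ]
    groups = [PATIENT] * config.n_patients + [CONTROL] * config.n_controls

    cols = {}
    for s, (sid, grp) in enumerate(zip(sample_ids, groups)):
        p = p_patient if grp == PATIENT else p_control
        mu = libsizes[s] * p
        cols[sid] = _nb_draw(rng, mu, phi)
    counts = pd.DataFrame(cols, index=mirnas)

    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "disease": config.disease}
    )
    truth = {mirnas[i]: float(lfc[i]) for i in de_idx}
    return SimulatedDataset(
        counts=CountMatrix(counts, pd.Series(libsizes.astype(float), index=sample_ids)),
        sample_sheet=sheet,
        truth=truth,
    )


def simulate_null(config: SimulationConfig) -> SimulatedDataset:
    """Same design with no truly differential miRNAs (frac_de forced to 0)."""
    return simulate_counts(replace(config, frac_de=0.0))


def simulate_edge_lists(
    n_mirnas: int,
    n_genes: int,
    n_databases: int,
    density: float,
    seed: int = 0,
    shared_frac: float = 0.1,
) -> list[pd.DataFrame]:
    """Per-database miRNA->gene edge tables with scores in [0, 1].

    Each possible (miRNA, gene) pair enters each database independently with
    probability ``density``; in addition a ``shared_frac`` fraction of pairs is
    planted in every database so that support ranking is exercised.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if n_databases < 1:
        raise ValueError("at least one database is required")
    rng = np.random.default_rng(seed)
    mirnas = np.array([f"mir-{i:05d}" for i in range(n_mirnas)])
    genes = np.array([f"GENE{j:05d}" for j in range(n_genes)])
    n_pairs = n_mirnas * n_genes
    n_shared = int(round(shared_frac * n_pairs))
    shared = set(rng.choice(n_pairs, size=n_shared, replace=False).tolist())

    tables = []
    for d in range(n_databases):
        mask = rng.random(n_pairs) < density
        idx = np.flatnonzero(mask)
        idx = np.union1d(idx, np.fromiter(shared, dtype=int)) if shared else idx
        mi, gi = np.divmod(idx, n_genes)
        tables.append(
            pd.DataFrame(
                {
                    "mirna_id": mirnas[mi],
                    "gene_id": genes[gi],
                    "score": rng.uniform(0.0, 1.0, size=idx.size),
                    "source_db": f"db{d + 1}",
                }
            )
        )
    return tables


def simulate_annotations(
    genes: list[str],
    n_terms: int,
    mean_terms_per_gene: float = 3.0,
    seed: int = 0,
    term_prefix: str = "GO:",
) -> pd.DataFrame:
    """Random gene -> term annotation table (gene_id, term_id, term_name)."""
    rng = np.random.default_rng(seed)
    terms = [f"{term_prefix}{i:07d}" for i in range(n_terms)]
    rows = []
    for g in genes:
        k = min(n_terms, rng.poisson(mean_terms_per_gene))
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append((g, terms[t], f"term {t}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).drop_duplicates(
        subset=["gene_id", "term_id"], ignore_index=True
    )


def simulate_ontology(
    term_ids: list[str], seed: int = 0, root: str | None = None
) -> pd.DataFrame:
    """Random rooted tree over terms as a (child_id, parent_id) edge list."""
    rng = np.random.default_rng(seed)
    nodes = list(term_ids)
    if root is None:
        root = nodes[0]
        children = nodes[1:]
    else:
        children = [t for t in nodes if t != root]
    placed = [root]
    rows = []
    for child in children:
        parent = placed[int(rng.integers(0, len(placed)))]
        rows.append((child, parent))
        placed.append(child)
    return pd.DataFrame(rows, columns=["child_id", "parent_id"])


def simulate_biotypes(
    feature_ids: list[str],
    seed: int = 0,
    class_probs: dict[str, float] | None = None,
) -> pd.Series:
    """Random small-RNA class labels for a composition report fixture."""
    probs = class_probs or {
        "miRNA": 0.55,
        "lncRNA": 0.12,
        "tRNA": 0.12,
        "snoRNA": 0.08,
        "snRNA": 0.05,
        "other": 0.08,
    }
    rng = np.random.default_rng(seed)
    classes = list(probs)
    p = np.array([probs[c] for c in classes], dtype=float)
    p = p / p.sum()
    labels = rng.choice(classes, size=len(feature_ids), p=p)
    return pd.Series(labels, index=pd.Index(feature_ids, name="feature_id"), name="class")
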