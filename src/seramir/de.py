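"""Negative-binomial quasi-likelihood differential expression for small-RNA counts.

The analysis pipeline is the classical bulk count workflow for a two-group
(patient vs control) comparison:

1. low-expression filtering on counts-per-million (CPM),
2. TMM (trimmed mean of M-values) normalization of library sizes,
3. NB generalized linear models with a log link and library-size offsets,
4. dispersion estimation (common / trended / tagwise via Cox-Reid adjusted
   profile likelihood, plus quasi-likelihood dispersions squeezed by
   empirical Bayes),
5. a quasi-likelihood F-test per miRNA with Benjamini-Hochberg FDR.

All estimators here are written against the published definitions of TMM and
the NB quasi-likelihood framework; bit-equality with any particular existing
implementation is not a goal — correctness is asserted through calibration
and parameter-recovery simulations plus small brute-force oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizationResult",
    "DispersionFit",
    "DEResult",
    "DESummary",
    "compute_cpm",
    "filter_low_expression",
    "tmm_factors",
    "tmm_factor_for_sample",
    "fit_dispersions",
    "ql_f_test",
    "run_de",
    "bh_fdr",
    "summarize_de",
    "volcano_classes",
    "zscore_matrix",
    "pca_variance",
    "average_log_cpm",
]

PATIENT = "patient"
CONTROL = "control"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer counts, miRNAs (rows) x samples (columns).

    ``library_sizes`` defaults to the column sums but may be supplied, e.g.
    when the matrix is a filtered subset of a larger quantification.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA identifiers: {dup[:5]}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if not np.allclose(values, np.round(values)):
            raise ValueError("count matrix contains non-integer entries")
        self.counts = counts.astype(np.int64)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=float).reindex(
                counts.columns
            )
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes missing for some samples")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0].tolist()
            raise ValueError(f"non-positive library sizes for samples: {bad}")

    @property
    def mirnas(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.library_sizes[list(samples)])

    def subset_mirnas(self, mirnas) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(mirnas)], self.library_sizes)


@dataclass
class NormalizationResult:
    """Per-sample TMM scaling factors (geometric mean 1) and effective sizes."""

    factors: pd.Series
    effective_library_sizes: pd.Series
    reference_sample: str
    # divisor used to re-center raw factors; needed to scale held-out samples
    centering_constant: float = 1.0


@dataclass
class DispersionFit:
    common: float
    trended: pd.Series
    tagwise: pd.Series
    raw: pd.Series
    ql_dispersion: pd.Series = None  # type: ignore[assignment]
    ql_prior_df: float = np.nan
    residual_df: pd.Series = None  # type: ignore[assignment]
    average_log_cpm: pd.Series = None  # type: ignore[assignment]


@dataclass
class DEResult:
    """Per-miRNA log2FC, logCPM, QL F statistic, p-value and BH FDR."""

    table: pd.DataFrame  # columns: log2FC, logCPM, F, p_value, FDR
    n_not_converged: int = 0

    def sorted(self) -> pd.DataFrame:
        """Deterministic ranking: ascending p, then larger |log2FC|, then ID."""
        t = self.table.copy()
        order = np.lexsort(
            (t.index.to_numpy(), -t["log2FC"].abs().to_numpy(), t["p_value"].to_numpy())
        )
        return t.iloc[order]


@dataclass
class DESummary:
    n_tested: int
    n_significant: int
    percent_significant: float
    n_over: int | None = None
    n_under: int | None = None
    n_fdr_significant: int | None = None


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------


def compute_cpm(
    counts: CountMatrix, norm: NormalizationResult | None = None
) -> pd.DataFrame:
    """Counts per million, using effective library sizes when ``norm`` is given."""
    lib = (
        norm.effective_library_sizes.reindex(counts.samples)
        if norm is not None
        else counts.library_sizes
    )
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive for CPM")
    return counts.counts / lib.to_numpy() * 1e6


def filter_low_expression(
    counts: CountMatrix, min_cpm: float = 1.0, min_libraries: int = 2
) -> CountMatrix:
    """Retain miRNAs with CPM >= ``min_cpm`` in at least ``min_libraries`` samples.

    CPM is computed once from the raw library sizes (filtering precedes
    normalization). Sample set and library sizes are unchanged.
    """
    if min_cpm <= 0 or min_libraries <= 0:
        raise ValueError("filter thresholds must be positive")
    cpm = compute_cpm(counts)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_libraries
    if not keep.any():
        warnings.warn("low-expression filter removed every miRNA", stacklevel=2)
    return CountMatrix(counts.counts.loc[keep], counts.library_sizes)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> float:
    """Raw (uncentered) TMM factor of one observation column against a reference.

    Doubly trimmed (30% of M extremes, 5% of A extremes) precision-weighted
    mean of log2 ratios of proportions; weights are inverse asymptotic
    (delta-method) variances of M.
    """
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        warnings.warn("no overlapping nonzero miRNAs with reference; factor set to 1")
        return 1.0
    o = obs[ok] / n_obs
    r = ref[ok] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    v = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])

    n = m.size
    if n == 1:
        return float(2.0 ** m[0])
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abundance_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))
    if not np.isfinite(f) or f <= 0:
        return 1.0
    return f


def _choose_reference(counts: CountMatrix) -> str:
    cpm = compute_cpm(counts)
    q75 = cpm.quantile(0.75, axis=0)
    return str((q75 - q75.mean()).abs().idxmin())


def tmm_factors(counts: CountMatrix) -> NormalizationResult:
    """TMM scaling factors, re-centered so their geometric mean is 1.

    Reference sample: the one whose upper-quartile CPM is closest to the mean
    upper-quartile across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    ref_id = _choose_reference(counts)
    ref = counts.counts[ref_id].to_numpy(dtype=float)
    n_ref = float(counts.library_sizes[ref_id])

    raw = {}
    for s in counts.samples:
        if s == ref_id:
            raw[s] = 1.0
        else:
            raw[s] = _tmm_pair_factor(
                counts.counts[s].to_numpy(dtype=float),
                ref,
                float(counts.library_sizes[s]),
                n_ref,
            )
    factors = pd.Series(raw, dtype=float).reindex(counts.samples)
    center = float(np.exp(np.mean(np.log(factors))))
    factors = factors / center
    eff = counts.library_sizes * factors
    return NormalizationResult(
        factors=factors,
        effective_library_sizes=eff,
        reference_sample=ref_id,
        centering_constant=center,
    )


def tmm_factor_for_sample(
    new_counts: pd.Series, new_libsize: float, train: CountMatrix, norm: NormalizationResult
) -> float:
    """TMM factor for a sample not seen during normalization.

    Computed against the training reference sample and re-centered with the
    training centering constant, so held-out samples share the training scale.
    Used to apply training-derived scaling inside cross-validation folds.
    """
    ref_id = norm.reference_sample
    obs = new_counts.reindex(train.mirnas).fillna(0).to_numpy(dtype=float)
    ref = train.counts[ref_id].to_numpy(dtype=float)
    f = _tmm_pair_factor(obs, ref, float(new_libsize), float(train.library_sizes[ref_id]))
    return f / norm.centering_constant


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across miRNAs)
# ---------------------------------------------------------------------------


def _group_indicator(sample_sheet: pd.DataFrame, samples: pd.Index) -> np.ndarray:
    sheet = sample_sheet.set_index("sample_id").reindex(samples)
    if sheet["group"].isna().any():
        missing = samples[sheet["group"].isna()].tolist()
        raise ValueError(f"samples missing from sample sheet: {missing}")
    bad = ~sheet["group"].isin([PATIENT, CONTROL])
    if bad.any():
        raise ValueError(f"unknown group labels: {sheet['group'][bad].unique().tolist()}")
    x = (sheet["group"] == PATIENT).to_numpy(dtype=float)
    if x.sum() == 0 or x.sum() == len(x):
        raise ValueError("both patient and control samples are required")
    return x


def _irls_two_group(
    y: np.ndarray,
    offset: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray | float,
    max_iter: int = 60,
    tol: float = 1e-10,
):
    """Fit per-gene NB GLMs mu = exp(b0 + b1*x + offset) by Fisher scoring.

    ``y`` is genes x samples; ``phi`` is a scalar or per-gene vector. Returns
    (beta (G,2), mu (G,n), converged (G,) bool).
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))[:, None]
    # initial values from group means of y/exp(offset)
    rate = y / np.exp(offset)[None, :]
    m0 = rate[:, x == 0].mean(axis=1)
    m1 = rate[:, x == 1].mean(axis=1)
    floor = 1e-8
    b0 = np.log(np.maximum(m0, floor))
    b1 = np.log(np.maximum(m1, floor)) - b0
    beta = np.stack([b0, b1], axis=1)
    converged = np.zeros(G, dtype=bool)
    mu = None
    for _ in range(max_iter):
        eta = beta[:, [0]] + beta[:, [1]] * x[None, :] + offset[None, :]
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (y - mu) / mu  # working residual on the link scale
        a00 = w.sum(axis=1)
        a01 = (w * x[None, :]).sum(axis=1)
        a11 = a01  # x is 0/1 so x^2 = x
        g0 = (w * z).sum(axis=1)
        g1 = (w * z * x[None, :]).sum(axis=1)
        det = a00 * a11 - a01 * a01
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        d0 = (a11 * g0 - a01 * g1) / det
        d1 = (a00 * g1 - a01 * g0) / det
        d0 = np.nan_to_num(d0, nan=0.0)
        d1 = np.nan_to_num(d1, nan=0.0)
        step = np.clip(np.stack([d0, d1], axis=1), -5.0, 5.0)
        beta = beta + step
        converged = np.max(np.abs(step), axis=1) < tol
        if converged.all():
            break
    eta = np.clip(beta[:, [0]] + beta[:, [1]] * x[None, :] + offset[None, :], -50.0, 50.0)
    mu = np.exp(eta)
    return beta, mu, converged


def _irls_intercept(
    y: np.ndarray, offset: np.ndarray, phi: np.ndarray | float, max_iter: int = 60,
    tol: float = 1e-10,
):
    """Intercept-only NB GLM fits (null model)."""
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))[:, None]
    rate = (y / np.exp(offset)[None, :]).mean(axis=1)
    b = np.log(np.maximum(rate, 1e-8))
    for _ in range(max_iter):
        eta = np.clip(b[:, None] + offset[None, :], -50.0, 50.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        step = np.clip((w * (y - mu) / mu).sum(axis=1) / w.sum(axis=1), -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(np.clip(b[:, None] + offset[None, :], -50.0, 50.0))
    return b, mu


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples (Poisson limit at phi=0)."""
    y = np.asarray(y, dtype=float)
    G = y.shape[0]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))[:, None]
    mu = np.maximum(mu, 1e-300)
    out = np.empty(y.shape)
    poisson = (phi <= 1e-12)[:, 0]
    if poisson.any():
        yp, mp = y[poisson], mu[poisson]
        out[poisson] = yp * np.log(mp) - mp - special.gammaln(yp + 1.0)
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        yn, mn = y[nb], mu[nb]
        out[nb] = (
            special.gammaln(yn + r)
            - special.gammaln(r)
            - special.gammaln(yn + 1.0)
            + yn * np.log(phi[nb] * mn)
            - (yn + r) * np.log1p(phi[nb] * mn)
        )
    return out.sum(axis=1)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Per-gene NB residual deviance (2 * (saturated - fitted log-likelihood))."""
    y = np.asarray(y, dtype=float)
    G = y.shape[0]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))[:, None]
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        small = phi <= 1e-12
        phi_safe = np.where(small, 1.0, phi)
        nb_term = (y + 1.0 / phi_safe) * np.log1p(phi * y) - (
            y + 1.0 / phi_safe
        ) * np.log1p(phi * mu)
        pois_term = -(y - mu)
        term2 = np.where(small, pois_term, -nb_term)
    dev = 2.0 * (term1 + term2)
    return np.maximum(dev, 0.0).sum(axis=1)


def _cr_adjusted_profile_loglik(
    y: np.ndarray, offset: np.ndarray, x: np.ndarray, phi: float
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of the dispersion, per gene.

    APL(phi) = loglik(phi, beta_hat(phi)) - 0.5 * log det(X' W X), with W the
    Fisher information weights mu/(1 + phi*mu) of the log-link NB GLM.
    """
    beta, mu, _ = _irls_two_group(y, offset, x, phi)
    ll = _nb_loglik(y, mu, phi)
    w = mu / (1.0 + phi * mu)
    a00 = w.sum(axis=1)
    a01 = (w * x[None, :]).sum(axis=1)
    det = np.maximum(a00 * a01 - a01 * a01, 1e-300)  # x binary: a11 == a01
    return ll - 0.5 * np.log(det)


_PHI_GRID = np.exp(np.linspace(np.log(1e-5), np.log(16.0), 41))


def _interp_argmax(grid_log: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Quadratic-interpolated argmax of rows of ``values`` on a log-phi grid."""
    idx = np.argmax(values, axis=-1)
    idx = np.clip(idx, 1, values.shape[-1] - 2)
    rows = np.arange(values.shape[0]) if values.ndim == 2 else None
    if values.ndim == 1:
        f0, f1, f2 = values[idx - 1], values[idx], values[idx + 1]
        x0, x1, x2 = grid_log[idx - 1], grid_log[idx], grid_log[idx + 1]
    else:
        f0, f1, f2 = values[rows, idx - 1], values[rows, idx], values[rows, idx + 1]
        x0, x1, x2 = grid_log[idx - 1], grid_log[idx], grid_log[idx + 1]
    denom = (f0 - 2 * f1 + f2)
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (f0 - f2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    h = x1 - x0
    return np.exp(x1 + shift * h)


def average_log_cpm(counts: CountMatrix, prior_count: float = 2.0) -> pd.Series:
    """log2 of the average CPM with a small prior, per miRNA."""
    lib = counts.library_sizes.to_numpy()
    prior = prior_count * lib / lib.mean()
    cpm = (counts.counts.to_numpy() + prior[None, :]) / (lib + 2 * prior)[None, :] * 1e6
    return pd.Series(np.log2(cpm.mean(axis=1)), index=counts.mirnas)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-8 * np.maximum(y, 1.0)):
            break
    return y


def _squeeze_var(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeezing of sample variances toward a common prior.

    Fits a scaled F distribution to the quasi-dispersions via moments of
    log(s2) and returns (posterior values, prior df, prior value).
    """
    ok = (df > 0) & np.isfinite(s2)
    s2w = np.maximum(s2[ok], 1e-10)
    dfw = df[ok]
    if s2w.size < 2:
        return s2.copy(), np.inf, float(np.median(s2w)) if s2w.size else 1.0
    z = np.log(s2w)
    e = z - special.digamma(dfw / 2.0) + np.log(dfw / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, dfw / 2.0))
    if evar > 0:
        df_prior = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    if np.isfinite(df_prior):
        post = (df * s2 + df_prior * s2_prior) / (df + df_prior)
        post = np.where(df + df_prior > 0, post, s2_prior)
    else:
        post = np.full_like(s2, s2_prior)
    return post, df_prior, s2_prior


def fit_dispersions(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    norm: NormalizationResult,
    prior_df: float = 10.0,
    n_bins: int = 20,
) -> DispersionFit:
    """Estimate common, trended, tagwise and quasi-likelihood dispersions.

    Common and per-bin dispersions maximize the summed Cox-Reid adjusted
    profile likelihood on a shared log-spaced grid; the trend is a moving
    average over average-logCPM bins; tagwise values shrink the per-gene
    estimates toward the trend with weight residual_df/(residual_df+prior_df).
    """
    y = counts.counts.to_numpy(dtype=float)
    G, n = y.shape
    x = _group_indicator(sample_sheet, counts.samples)
    if n - 2 < 3:
        raise ValueError("at least 3 residual degrees of freedom are required")
    offset = np.log(norm.effective_library_sizes.reindex(counts.samples).to_numpy())

    grid = _PHI_GRID
    apl = np.empty((G, grid.size))
    for j, phi in enumerate(grid):
        apl[:, j] = _cr_adjusted_profile_loglik(y, offset, x, float(phi))
    log_grid = np.log(grid)

    common = float(_interp_argmax(log_grid, apl.sum(axis=0)))
    raw = _interp_argmax(log_grid, apl)

    ave_lcpm = average_log_cpm(counts)
    order = np.argsort(ave_lcpm.to_numpy(), kind="stable")
    n_bins_eff = max(1, min(n_bins, G // 5)) if G >= 5 else 1
    bins = np.array_split(order, n_bins_eff)
    bin_phi = np.array(
        [float(_interp_argmax(log_grid, apl[b].sum(axis=0))) for b in bins]
    )
    # moving average over bins (window 3), then interpolate per gene on logCPM
    if bin_phi.size >= 3:
        padded = np.concatenate([bin_phi[:1], bin_phi, bin_phi[-1:]])
        bin_smooth = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    else:
        bin_smooth = bin_phi
    bin_x = np.array([ave_lcpm.to_numpy()[b].mean() for b in bins])
    if bin_x.size > 1:
        trended = np.interp(ave_lcpm.to_numpy(), bin_x, bin_smooth)
    else:
        trended = np.full(G, bin_smooth[0])

    df_res = float(n - 2)
    shrink = df_res / (df_res + prior_df) if np.isfinite(prior_df) else 0.0
    tagwise = trended + (raw - trended) * shrink

    # quasi-likelihood dispersions from deviance residuals at the trended NB fit
    _, mu, _ = _irls_two_group(y, offset, x, trended)
    dev = _nb_deviance(y, mu, trended)
    zero_groups = np.zeros(G)
    for g_val, n_g in ((0.0, int((x == 0).sum())), (1.0, int((x == 1).sum()))):
        allzero = (y[:, x == g_val] == 0).all(axis=1)
        zero_groups += np.where(allzero, n_g - 1, 0.0)
    df_g = np.maximum(n - 2 - zero_groups, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df_g > 0, dev / np.maximum(df_g, 1.0), np.nan)
    s2_post, ql_prior_df, _ = _squeeze_var(s2, df_g)
    s2_post = np.where(np.isfinite(s2_post), s2_post, 1.0)

    idx = counts.mirnas
    return DispersionFit(
        common=common,
        trended=pd.Series(trended, index=idx),
        tagwise=pd.Series(tagwise, index=idx),
        raw=pd.Series(raw, index=idx),
        ql_dispersion=pd.Series(s2_post, index=idx),
        ql_prior_df=ql_prior_df,
        residual_df=pd.Series(df_g, index=idx),
        average_log_cpm=ave_lcpm,
    )


def ql_f_test(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    norm: NormalizationResult,
    dispersions: DispersionFit,
    prior_count: float = 0.125,
) -> DEResult:
    """Quasi-likelihood F-test of patient vs control, per miRNA.

    F = (deviance drop of the group term) / (squeezed QL dispersion), referred
    to an F distribution with 1 and (residual + prior) degrees of freedom.
    log2FC is the group coefficient of a fit on library-size-scaled
    prior-augmented counts, which keeps fold changes finite at zero counts.
    """
    y = counts.counts.to_numpy(dtype=float)
    x = _group_indicator(sample_sheet, counts.samples)
    offset = np.log(norm.effective_library_sizes.reindex(counts.samples).to_numpy())
    phi = dispersions.trended.reindex(counts.mirnas).to_numpy()

    _, mu_full, conv = _irls_two_group(y, offset, x, phi)
    _, mu_null = _irls_intercept(y, offset, phi)
    dev_full = _nb_deviance(y, mu_full, phi)
    dev_null = _nb_deviance(y, mu_null, phi)
    drop = np.maximum(dev_null - dev_full, 0.0)

    s2 = dispersions.ql_dispersion.reindex(counts.mirnas).to_numpy()
    df_g = dispersions.residual_df.reindex(counts.mirnas).to_numpy()
    f_stat = drop / np.maximum(s2, 1e-10)
    df_total = df_g + dispersions.ql_prior_df
    if np.isfinite(dispersions.ql_prior_df):
        p = stats.f.sf(f_stat, 1.0, np.maximum(df_total, 1e-8))
    else:
        p = stats.chi2.sf(f_stat, 1.0)

    n_bad = int((~conv).sum())
    if n_bad:
        warnings.warn(f"{n_bad} miRNA GLM fits did not converge; p set to 1")
        p = np.where(conv, p, 1.0)
        f_stat = np.where(conv, f_stat, 0.0)

    # shrunken log2FC from prior-augmented counts
    lib = np.exp(offset)
    prior = prior_count * lib / lib.mean()
    y_aug = y + prior[None, :]
    offset_aug = np.log(lib + 2.0 * prior)
    beta_aug, _, _ = _irls_two_group(y_aug, offset_aug, x, phi)
    log2fc = beta_aug[:, 1] / np.log(2.0)

    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "logCPM": dispersions.average_log_cpm.reindex(counts.mirnas).to_numpy(),
            "F": f_stat,
            "p_value": np.clip(p, 0.0, 1.0),
            "FDR": bh_fdr(np.clip(p, 0.0, 1.0)),
        },
        index=counts.mirnas,
    )
    return DEResult(table=table, n_not_converged=n_bad)


def run_de(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    min_cpm: float = 1.0,
    min_libraries: int = 2,
    prior_df: float = 10.0,
) -> DEResult:
    """Full pipeline: filter -> TMM -> dispersions -> QL F-test."""
    filtered = filter_low_expression(counts, min_cpm=min_cpm, min_libraries=min_libraries)
    if filtered.shape[0] == 0:
        raise ValueError("no miRNAs pass the expression filter")
    norm = tmm_factors(filtered)
    disp = fit_dispersions(filtered, sample_sheet, norm, prior_df=prior_df)
    return ql_f_test(filtered, sample_sheet, norm, disp)


# ---------------------------------------------------------------------------
# multiple testing, summaries, descriptive outputs
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _round_half_away(x: float, decimals: int = 1) -> float:
    scale = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale)


def summarize_de(
    de: DEResult | None = None,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    n_tested: int | None = None,
    n_significant: int | None = None,
) -> DESummary:
    """Counts and 1-decimal percentage of significant miRNAs.

    Significance: p < ``p_thresh`` and |log2FC| > ``lfc_thresh``. Also usable
    in reporting mode from bare integers (``n_tested``, ``n_significant``),
    e.g. to recompute a printed percentage from printed counts.
    """
    if de is None:
        if n_tested is None or n_significant is None:
            raise ValueError("provide a DEResult or both n_tested and n_significant")
        if n_tested <= 0:
            raise ValueError("n_tested must be positive")
        pct = _round_half_away(100.0 * n_significant / n_tested, 1)
        return DESummary(n_tested=n_tested, n_significant=n_significant, percent_significant=pct)
    t = de.table
    if len(t) == 0:
        raise ValueError("empty DE result")
    sig = (t["p_value"] < p_thresh) & (t["log2FC"].abs() > lfc_thresh)
    n_over = int((sig & (t["log2FC"] > 0)).sum())
    n_under = int((sig & (t["log2FC"] < 0)).sum())
    n_sig = int(sig.sum())
    return DESummary(
        n_tested=len(t),
        n_significant=n_sig,
        percent_significant=_round_half_away(100.0 * n_sig / len(t), 1),
        n_over=n_over,
        n_under=n_under,
        n_fdr_significant=int((t["FDR"] < 0.05).sum()),
    )


def volcano_classes(
    de: DEResult, p_thresh: float = 0.05, lfc_thresh: float = 1.0
) -> pd.Series:
    """Per-miRNA volcano label: 'over', 'under' or 'ns'."""
    t = de.table
    sig = t["p_value"] < p_thresh
    labels = np.where(
        sig & (t["log2FC"] > lfc_thresh),
        "over",
        np.where(sig & (t["log2FC"] < -lfc_thresh), "under", "ns"),
    )
    return pd.Series(labels, index=t.index, name="volcano_class")


def zscore_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores: subtract the row mean, divide by the row sd (n-1).

    Constant rows map to all-zero by convention.
    """
    if values.shape[1] < 2:
        raise ValueError("Z-scores require at least two samples")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (arr - mean) / sd, 0.0)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def pca_variance(expression: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    """Percent variance per principal component over samples, descending.

    ``expression`` is features x samples; PCA is run on the centered sample
    profiles.
    """
    from sklearn.decomposition import PCA

    if expression.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    x = expression.to_numpy(dtype=float).T
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValueError("zero-variance input; PCA is degenerate")
    k = max(1, min(n_components, x.shape[0] - 1, x.shape[1]))
    pca = PCA(n_components=k)
    pca.fit(x)
    return pca.explained_variance_ratio_ * 100.0
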