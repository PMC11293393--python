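"""Normalization factors, NB differential testing, and EM multimapper
assignment.

The differential test is a negative-binomial likelihood-ratio test with a
method-of-moments dispersion per feature shrunk toward the common
dispersion with weight n / (n + 4). Fold changes are computed on the
normalized scale with a per-sample-scaled prior count so features with
zeros get finite, comparable log2FC, and significance defaults to
FDR < 0.05 with |log2FC| > 0.9.

Multimapping reads are assigned fractionally by EM on the standard mixture
model: a read's posterior over its compatible features is proportional to
the current abundance estimates, abundances are re-estimated from the
fractional assignments, and the loop repeats until the abundances stop
moving. Total fractional mass always equals the number of reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .signal import CountMatrix


@dataclass
class NormalizationFactors:
    """Per-sample effective size factors (denominator x compositional)."""

    effective: pd.Series  # per-sample effective size factor
    compositional: pd.Series  # TMM part, geometric mean 1
    method: str

    def __post_init__(self) -> None:
        if (self.effective <= 0).any():
            raise ValueError("factors must be > 0")
        log_mean = float(np.log(self.compositional).mean())
        if abs(log_mean) > 1e-6:
            raise ValueError("compositional factors must have geometric mean 1")


def trimmed_mean_factors(
    matrix: CountMatrix,
    ref_sample: str | None = None,
    mode: str = "library_size",
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> NormalizationFactors:
    """TMM compositional factors combined with the chosen denominator.

    Per sample, M-values (log2 ratio of depth-normalized counts vs the
    reference) and A-values (mean log2 abundance) are computed over features
    nonzero in both samples; the most extreme ``logratio_trim`` fraction of
    M and ``abundance_trim`` fraction of A are discarded and the factor is
    2^mean(M) of the rest. Factors are renormalized to geometric mean 1 and
    multiplied by the denominator (library or spike-in size).
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    denom = matrix.denominators(mode)
    if ref_sample is None:
        ref_sample = counts.columns[0]
    ref = counts[ref_sample].to_numpy(dtype=float)
    ref_d = float(denom[ref_sample])
    comp = {}
    for s in counts.columns:
        if s == ref_sample:
            comp[s] = 1.0
            continue
        obs = counts[s].to_numpy(dtype=float)
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            raise ValueError(f"sample {s} shares no nonzero features with reference")
        obs_p = obs[ok] / float(denom[s])
        ref_p = ref[ok] / ref_d
        M = np.log2(obs_p / ref_p)
        A = 0.5 * (np.log2(obs_p) + np.log2(ref_p))
        keep = np.ones(len(M), dtype=bool)
        for vals, trim in ((M, logratio_trim), (A, abundance_trim)):
            lo, hi = np.quantile(vals, [trim / 2, 1 - trim / 2])
            keep &= (vals >= lo) & (vals <= hi)
        if not keep.any():
            keep[:] = True  # degenerate tiny fixtures: fall back to no trim
        comp[s] = float(2 ** np.mean(M[keep]))
    comp = pd.Series(comp)[counts.columns]
    comp = comp / np.exp(np.log(comp).mean())  # geometric mean 1
    effective = comp * denom
    return NormalizationFactors(
        effective=effective, compositional=comp, method=f"tmm/{mode}"
    )


# -------------------------------------------------------------- NB testing

def _fit_nb_mu(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """Per-feature MLE of the base mean mu with counts y_ij ~ NB(mu_i s_j).

    Newton iteration on the score equation, vectorized over features.
    ``y`` is features x samples, ``s`` length-samples, ``alpha`` per feature.
    """
    tot = y.sum(axis=1)
    mu = np.maximum(tot / s.sum(), 1e-8)
    a = alpha[:, None]
    for _ in range(n_iter):
        m = mu[:, None] * s[None, :]
        denom = 1.0 + a * m
        # score: sum_j s_j (y - m) / (m (1 + alpha m)) = sum_j (y - m) / (mu (1 + alpha m))
        score = ((y - m) / (mu[:, None] * denom)).sum(axis=1)
        # expected Fisher information for a stable Newton step
        info = (s[None, :] ** 2 / (m * denom)).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        mu_new = np.maximum(mu + step, 1e-10)
        if np.all(np.abs(mu_new - mu) <= 1e-10 + 1e-8 * mu):
            mu = mu_new
            break
        mu = mu_new
    return mu


def _moment_dispersion(
    y: np.ndarray, s: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Method-of-moments dispersion per feature on factor-normalized counts.

    Within each group, z = y/s has E[z] = mu and Var[z] ~= mu * E[1/s] +
    alpha * mu^2; the pooled excess variance over the Poisson part yields
    alpha. Raw per-feature estimates are returned unfloored (they can be
    negative) so that shrinkage toward the common value averages out their
    noise instead of accumulating the positive excursions; flooring happens
    after shrinkage. Returns (alpha_raw, num, den); the pooled-ratio common
    dispersion is num.sum()/den.sum() over informative features.
    """
    alpha_num = np.zeros(y.shape[0])
    alpha_den = np.zeros(y.shape[0])
    for g in np.unique(groups):
        idx = groups == g
        z = y[:, idx] / s[idx]
        n = idx.sum()
        mu = z.mean(axis=1)
        var = z.var(axis=1, ddof=1)
        pois = mu * np.mean(1.0 / s[idx])
        alpha_num += (var - pois) * (n - 1)
        alpha_den += np.maximum(mu, 1e-10) ** 2 * (n - 1)
    alpha_raw = alpha_num / np.maximum(alpha_den, 1e-300)
    return alpha_raw, alpha_num, alpha_den


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # baseMean, log2FC, pvalue, fdr, significant
    fdr_threshold: float
    lfc_threshold: float


def nb_differential(
    matrix: CountMatrix,
    groups: list[str],
    factors: NormalizationFactors | None = None,
    prior_count: float = 3.0,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.9,
    norm_mode: str = "library_size",
) -> DifferentialResult:
    """NB likelihood-ratio test between two groups of samples.

    Dispersion is a per-feature moment estimate shrunk toward the pooled
    common dispersion with weight df/(df+4), df being the residual degrees
    of freedom (samples minus the two group means); group means are NB MLEs
    given the effective size factors; the LRT statistic is referred to
    chi2(1). log2FC uses normalized group means with a per-sample-scaled
    prior. Features that are all-zero get p = 1 and log2FC = 0.
    """
    counts = matrix.counts
    groups = np.asarray(groups)
    if len(groups) != counts.shape[1]:
        raise ValueError("one group label per sample required")
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 samples")

    if factors is None:
        factors = trimmed_mean_factors(matrix, mode=norm_mode)
    s_raw = factors.effective[counts.columns].to_numpy(dtype=float)
    s = s_raw / s_raw.mean()  # relative effective factors, mean 1

    y = counts.to_numpy(dtype=np.int64)
    nz = y.sum(axis=1) > 0

    # dispersion: per-feature moments shrunk toward the pooled common value
    n = counts.shape[1]
    alpha_raw, a_num, a_den = _moment_dispersion(y, s, groups)
    common = (
        max(float(a_num[nz].sum() / a_den[nz].sum()), 0.0) if nz.any() else 0.0
    )
    df_res = n - 2
    w = df_res / (df_res + 4.0)
    alpha = np.maximum(w * alpha_raw + (1 - w) * common, 1e-8)

    mask1 = groups == uniq[0]
    mask2 = groups == uniq[1]
    mu0 = _fit_nb_mu(y, s, alpha)
    mu1 = _fit_nb_mu(y[:, mask1], s[mask1], alpha)
    mu2 = _fit_nb_mu(y[:, mask2], s[mask2], alpha)

    r = 1.0 / alpha

    def loglik(yy, mu, ss):
        m = np.maximum(mu[:, None] * ss[None, :], 1e-10)
        return stats.nbinom.logpmf(yy, r[:, None], r[:, None] / (r[:, None] + m)).sum(
            axis=1
        )

    ll_null = loglik(y, mu0, s)
    ll_alt = loglik(y[:, mask1], mu1, s[mask1]) + loglik(y[:, mask2], mu2, s[mask2])
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    pvalue = stats.chi2.sf(lrt, df=1)
    pvalue[~nz] = 1.0

    # prior-stabilized log2FC on the normalized scale
    prior = prior_count * s / s.mean()
    znorm = (y + prior[None, :]) / s[None, :]
    m1 = znorm[:, mask1].mean(axis=1)
    m2 = znorm[:, mask2].mean(axis=1)
    log2fc = np.log2(m2 / m1)
    log2fc[~nz] = 0.0

    fdr = multipletests(pvalue, method="fdr_bh")[1]
    base_mean = (y / s[None, :]).mean(axis=1)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
            "significant": (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold),
        },
        index=counts.index,
    )
    return DifferentialResult(
        table=table, fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold
    )


# ------------------------------------------------------------------- EM

@dataclass
class CompatibilityMatrix:
    """Sparse reads x features 0/1 compatibility."""

    matrix: sparse.csr_matrix
    features: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] == 0 or self.matrix.shape[1] == 0:
            raise ValueError("empty compatibility matrix")
        per_read = np.asarray(self.matrix.sum(axis=1)).ravel()
        if (per_read == 0).any():
            raise ValueError(
                f"{int((per_read == 0).sum())} read(s) compatible with no feature"
            )

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    def unique_mask(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel() == 1


def compatibility_from_lists(
    read_features: list[list[str]], features: list[str] | None = None
) -> CompatibilityMatrix:
    """Build the sparse matrix from per-read lists of compatible features."""
    if features is None:
        seen = {}
        for fl in read_features:
            for f in fl:
                seen.setdefault(f, None)
        features = list(seen)
    fidx = {f: i for i, f in enumerate(features)}
    rows, cols = [], []
    for ri, fl in enumerate(read_features):
        for f in set(fl):
            rows.append(ri)
            cols.append(fidx[f])
    m = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(read_features), len(features)),
    )
    return CompatibilityMatrix(matrix=m, features=features)


@dataclass
class EMResult:
    counts: pd.Series  # fractional counts per feature, sums to n_reads
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray


def em_assign_multireads(
    compat: CompatibilityMatrix, max_iter: int = 100, tol: float = 1e-6
) -> EMResult:
    """EM fractional assignment of multimapping reads to features.

    Abundances start uniform; each E-step splits a read over its compatible
    features proportional to current abundances, each M-step sets the
    abundances to the summed fractional assignments. Stops when the largest
    relative abundance change drops below ``tol``. The log-likelihood
    sum_r log(sum_f C_rf pi_f) is non-decreasing by construction.
    """
    C = compat.matrix.tocsr()
    n_reads, n_feat = C.shape
    pi = np.full(n_feat, 1.0 / n_feat)
    lls = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = C @ pi  # per-read total weight, > 0 by invariant
        lls.append(float(np.log(denom).sum()))
        # fractional counts: sum over reads of C_rf pi_f / denom_r
        frac = pi * np.asarray(C.T @ (1.0 / denom)).ravel()
        pi_new = frac / n_reads
        rel = np.abs(pi_new - pi) / np.maximum(pi, 1e-300)
        pi = pi_new
        if float(rel.max()) < tol:
            converged = True
            break
    counts = pd.Series(pi * n_reads, index=compat.features)
    return EMResult(
        counts=counts, n_iter=it, converged=converged, loglik_trace=np.array(lls)
    )


def rollup_counts(counts: pd.Series, feature_to_group: dict[str, str]) -> pd.Series:
    """Sum instance-level fractional counts up to family level."""
    groups = pd.Series(
        {f: feature_to_group.get(f, f) for f in counts.index}
    )
    return counts.groupby(groups).sum()
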