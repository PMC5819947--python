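"""Inferential machinery: Monte-Carlo permutation tests, Benjamini-
Hochberg FDR, cluster-size filtering of time-frequency masks,
single-trial power-velocity correlation maps, and normality-gated
clinical correlations.

Permutation p-values use the conservative (r+1)/(n+1) estimator with
two-sided counting of permuted |statistics| >= |observed|, so p is
never zero and the tests remain valid at finite permutation counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sp_stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

DEFAULT_N_PERM = 5000
DEFAULT_ALPHA = 0.05
MIN_CLUSTER_SIZE = 150


@dataclass
class StatResult:
    statistic: float
    p_value: float
    n_permutations: int
    family: str
    method: str = "permutation"
    extra: dict = field(default_factory=dict)


def _count_p(perm_stats: np.ndarray, observed: float, n_perm: int) -> float:
    tol = 1e-12 * max(1.0, abs(observed))
    r = int(np.sum(np.abs(perm_stats) >= abs(observed) - tol))
    return (r + 1) / (n_perm + 1)


def permutation_test(sample_a: np.ndarray, sample_b: np.ndarray | None = None,
                     family: str = "two_sample", n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = None) -> StatResult:
    """Monte-Carlo permutation test.

    Families
    --------
    ``paired``      sign-flip of within-unit differences a - b
    ``one_sample``  sign-flip of a single sample against zero
    ``two_sample``  label exchange between two independent samples

    The statistic is the difference of means (paired/one-sample: the
    mean difference); p is two-sided via symmetric absolute counting.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(sample_a, dtype=float)
    if family in ("paired", "one_sample"):
        if family == "paired":
            if sample_b is None:
                raise ValueError("paired test needs two samples")
            b = np.asarray(sample_b, dtype=float)
            if a.shape != b.shape:
                raise ValueError("paired samples must have equal length")
            d = a - b
        else:
            d = a
        if d.size < 2:
            raise ValueError("need at least 2 observations")
        obs = float(d.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        perm = (signs * d).mean(axis=1)
    elif family == "two_sample":
        if sample_b is None:
            raise ValueError("two-sample test needs two samples")
        b = np.asarray(sample_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 observations per sample")
        obs = float(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        n_a, n_tot = a.size, a.size + b.size
        perm = np.empty(n_perm)
        idx = np.arange(n_tot)
        for i in range(n_perm):
            rng.shuffle(idx)
            perm[i] = pooled[idx[:n_a]].mean() - pooled[idx[n_a:]].mean()
    else:
        raise ValueError(f"unknown test family {family!r}")
    p = _count_p(perm, obs, n_perm)
    return StatResult(statistic=obs, p_value=p, n_permutations=n_perm,
                      family=family)


def fdr_correct(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA
                ) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up; returns the significance mask and the
    realised p-threshold (largest p_(k) with p_(k) <= k*alpha/m, 0 if
    nothing survives)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    mask = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    threshold = float(p[mask].max()) if mask.any() else 0.0
    return mask, threshold


def cluster_filter(mask: np.ndarray, min_size: int = MIN_CLUSTER_SIZE
                   ) -> np.ndarray:
    """Remove connected components (4-connectivity, no diagonals) smaller
    than `min_size` bins from a boolean frequency x time mask."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def _spearman_map(power: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho across trials for every freq x time bin (vectorised).

    `power` is trials x freqs x times; bins with zero variance are NaN.
    """
    n = power.shape[0]
    rx = sp_stats.rankdata(power, axis=0)
    ry = sp_stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    sx = np.sqrt((rx ** 2).sum(axis=0))
    sy = np.sqrt((ry ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.einsum("kft,k->ft", rx, ry) / denom
    rho[denom == 0] = np.nan
    return rho


@dataclass
class CorrelationMap:
    """Group-level single-trial power-velocity correlation map."""

    rho: np.ndarray               # patients x freqs x times Spearman rho
    rho_mean: np.ndarray          # freqs x times
    p_values: np.ndarray          # freqs x times group sign-flip p
    mask_fdr: np.ndarray          # after FDR
    mask: np.ndarray              # after FDR + cluster filter
    freqs: np.ndarray
    times: np.ndarray
    excluded_patients: list = field(default_factory=list)


def tf_velocity_correlation(maps: list[np.ndarray], velocities: list[np.ndarray],
                            freqs: np.ndarray, times: np.ndarray,
                            n_perm: int = DEFAULT_N_PERM,
                            alpha: float = DEFAULT_ALPHA,
                            min_cluster_size: int = MIN_CLUSTER_SIZE,
                            seed: int | None = None) -> CorrelationMap:
    """Within-patient Spearman correlation of single-trial power with trial
    peak velocity in every time-frequency bin, tested at the group level
    with a one-sample sign-flip permutation test per bin, then FDR and
    cluster-size filtered.

    `maps` holds one trials x freqs x times percent-change array per
    patient; `velocities` the matching trial peak velocities.
    """
    rng = np.random.default_rng(seed)
    rhos, excluded = [], []
    for pi, (m, v) in enumerate(zip(maps, velocities)):
        v = np.asarray(v, dtype=float)
        if m.shape[0] < 5:
            excluded.append((pi, "fewer than 5 trials"))
            continue
        if np.ptp(v) == 0:
            excluded.append((pi, "constant velocity"))
            continue
        rhos.append(_spearman_map(np.asarray(m, dtype=float), v))
    if not rhos:
        raise ValueError("no usable patients")
    rho = np.stack(rhos)                       # P x F x T
    n_pat = rho.shape[0]
    flat = np.nan_to_num(rho.reshape(n_pat, -1), nan=0.0)
    obs = flat.mean(axis=0)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_pat))
    counts = np.zeros(flat.shape[1], dtype=np.int64)
    chunk = max(1, int(1e7) // max(n_perm, 1))
    for j0 in range(0, flat.shape[1], chunk):
        block = flat[:, j0:j0 + chunk]
        perm = signs @ block / n_pat           # n_perm x bins
        counts[j0:j0 + chunk] = (
            np.abs(perm) >= np.abs(block.mean(axis=0)) - 1e-12).sum(axis=0)
    p = ((counts + 1) / (n_perm + 1)).reshape(rho.shape[1:])
    mask_fdr, _ = fdr_correct(p.ravel(), alpha=alpha)
    mask_fdr = mask_fdr.reshape(p.shape)
    mask = cluster_filter(mask_fdr, min_size=min_cluster_size)
    return CorrelationMap(rho=rho, rho_mean=np.nanmean(rho, axis=0),
                          p_values=p, mask_fdr=mask_fdr, mask=mask,
                          freqs=np.asarray(freqs), times=np.asarray(times),
                          excluded_patients=excluded)


def correlate_clinical(scores: np.ndarray, values: np.ndarray,
                       alpha: float = DEFAULT_ALPHA) -> StatResult:
    """Correlation between a per-patient summary and a clinical score.

    Each variable is checked for normality with a Lilliefors-corrected
    Kolmogorov-Smirnov test; Pearson correlation is used when both pass,
    rank-based Spearman otherwise.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ValueError("need at least 5 complete patient pairs")
    normal = all(lilliefors(v, dist="norm")[1] > alpha for v in (x, y))
    if normal:
        r, p = sp_stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sp_stats.spearmanr(x, y)
        method = "spearman"
    return StatResult(statistic=float(r), p_value=float(p),
                      n_permutations=0, family="correlation", method=method,
                      extra={"n": int(x.size), "normal": bool(normal)})
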