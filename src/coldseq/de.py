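"""Negative-binomial exact-test differential expression.

Pairwise treatment-vs-control contrasts in the classical small-sample
style: TMM normalisation, a common NB dispersion estimated by maximising
the conditional likelihood on library-size-equalised pseudo-counts, and
a per-gene exact test of the treatment-group sum conditional on the
total. The conditional distribution of one group's sum given the total,
when both groups are NB with a common dispersion and equal effective
library sizes, is beta-binomial with shape parameters n_group/phi; its
tails are summed exactly from the log-pmf (vectorised over genes, the
shorter tail of each), and the phi -> 0 limit reduces to a conditional
binomial test computed with scipy's binom.

The model surface is `NBExactTest(counts, control, treatment).fit()`,
which returns a :class:`DEResults`; the free functions `tmm_factors`,
`estimate_common_dispersion`, `nb_exact_test`, `bh_fdr` and `count_degs`
expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .containers import ConfigError, CountMatrix

__all__ = [
    "tmm_factors",
    "estimate_common_dispersion",
    "DispersionEstimate",
    "NBExactTest",
    "DEResults",
    "nb_exact_test",
    "bh_fdr",
    "count_degs",
]

RESULT_COLUMNS = ["logFC", "logCPM", "PValue", "FDR"]


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim=0.3, sum_trim=0.05):
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M, used as inverse weight
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: CountMatrix, reference_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, one per sample.

    Log-ratios (M) are trimmed 30% each side and abundances (A) 5% each
    side; genes with a zero in either sample are excluded. Factors are
    rescaled so their geometric mean is 1.
    """
    lib = counts.library_sizes()
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ConfigError(f"sample {bad!r} has zero total count")
    mat = counts.counts.to_numpy(dtype=float)
    if reference_sample is None:
        # reference = sample whose upper-quartile CPM is closest to the mean
        uq = np.array(
            [np.quantile(mat[:, j] / lib.iloc[j], 0.75) for j in range(mat.shape[1])]
        )
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference_sample not in counts.sample_ids:
            raise ConfigError(f"unknown reference sample {reference_sample!r}")
        ref_j = counts.sample_ids.get_loc(reference_sample)

    ref = mat[:, ref_j]
    n_ref = lib.iloc[ref_j]
    raw = np.array(
        [_tmm_pair(mat[:, j], ref, lib.iloc[j], n_ref) for j in range(mat.shape[1])]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


# ---------------------------------------------------------------------------
# Common dispersion (conditional likelihood + golden-section search)
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    common: float
    method: str = "conditional-ml"
    tagwise: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.common) or self.common < 0:
            raise ConfigError("dispersion must be finite and >= 0")


def _pseudo_counts(
    counts: CountMatrix, norm_factors: pd.Series | None = None
) -> tuple[np.ndarray, pd.Series, float]:
    """Counts rescaled to a common (geometric-mean) effective library size."""
    lib = counts.library_sizes().astype(float)
    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    eff = lib * pd.Series(norm_factors, index=counts.sample_ids).astype(float)
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = counts.counts.to_numpy(dtype=float) * (common / eff.to_numpy())
    return pseudo, eff, common

def _group_cols(counts: CountMatrix, condition: str) -> np.ndarray:
    cols = np.array(
        [counts.sample_ids.get_loc(s) for s in counts.samples_of(condition)]
    )
    if cols.size == 0:
        raise ConfigError(f"unknown or empty condition {condition!r}")
    return cols


def _conditional_ll(pseudo_groups, phi: float) -> float:
    """Conditional NB log-likelihood (terms depending on phi only)."""
    r = 1.0 / phi
    total = 0.0
    for y in pseudo_groups:  # y: genes x reps of one group
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.size * gammaln(r)
            + z.size * gammaln(n * r) - np.sum(gammaln(z + n * r))
        )
    return total


def _golden_max(f, lo: float, hi: float, tol: float = 1e-8, max_iter: int = 200):
    """Golden-section maximisation of a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = 0.5 * (a + b)
    # the maximiser may sit on a boundary of the search interval
    for edge in (lo, hi):
        if f(edge) > f(x):
            x = edge
    return x


def estimate_common_dispersion(
    counts: CountMatrix, conditions: tuple[str, str],
    norm_factors: pd.Series | None = None,
) -> DispersionEstimate:
    """Common NB dispersion shared by all genes of a two-group contrast.

    Maximises the conditional log-likelihood (each group's replicate
    vector conditional on its sum, library sizes equalised via TMM
    pseudo-counts) by golden-section search on phi in [1e-6, 10].
    """
    sub = counts.subset_conditions(conditions)
    cols = [_group_cols(sub, c) for c in conditions]
    if all(c.size < 2 for c in cols):
        raise ConfigError("dispersion not estimable: no condition has >= 2 replicates")
    if norm_factors is not None:
        norm_factors = pd.Series(norm_factors, index=counts.sample_ids)[sub.sample_ids]
    pseudo, _, _ = _pseudo_counts(sub, norm_factors)
    keep = pseudo.sum(axis=1) > 0
    groups = [pseudo[keep][:, c] for c in cols]
    phi = _golden_max(lambda p: _conditional_ll(groups, p), 1e-6, 10.0)
    return DispersionEstimate(common=float(phi))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _betabinom_logpmf(y, z, a, b):
    """log P(Y=y) for Y ~ BetaBinom(n=z, a, b), all arguments array-like."""
    return (
        gammaln(z + 1) - gammaln(y + 1) - gammaln(z - y + 1)
        + gammaln(y + a) + gammaln(z - y + b) - gammaln(z + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def _betabinom_tails(s, z, a, b, chunk=2_000_000):
    """Exact lower/upper tail probabilities of BetaBinom(z, a, b) at s.

    For each gene the shorter tail is summed directly (vectorised over a
    flattened ragged layout, processed in chunks to bound memory); the
    opposite tail is recovered as 1 - tail + pmf(s).
    """
    s = np.asarray(s, dtype=np.int64)
    z = np.asarray(z, dtype=np.int64)
    lower = np.empty(s.size)
    upper = np.empty(s.size)
    use_lower = s <= z - s  # sum whichever side has fewer terms
    seg_len = np.where(use_lower, s + 1, z - s + 1)
    pmf_s = np.exp(_betabinom_logpmf(s.astype(float), z.astype(float), a, b))

    order = np.arange(s.size)
    start = 0
    while start < s.size:
        stop = start + 1
        total = seg_len[start]
        while stop < s.size and total + seg_len[stop] <= chunk:
            total += seg_len[stop]
            stop += 1
        idx = order[start:stop]
        m = seg_len[idx]
        offsets = np.concatenate(([0], np.cumsum(m)[:-1]))
        flat_pos = np.arange(m.sum()) - np.repeat(offsets, m)
        y0 = np.where(use_lower[idx], 0, z[idx] - m + 1)
        y = np.repeat(y0, m) + flat_pos
        lp = _betabinom_logpmf(
            y.astype(float), np.repeat(z[idx], m).astype(float), a, b
        )
        seg_sum = np.add.reduceat(np.exp(lp), offsets)
        direct = np.minimum(seg_sum, 1.0)
        other = np.minimum(1.0 - direct + pmf_s[idx], 1.0)
        lower[idx] = np.where(use_lower[idx], direct, other)
        upper[idx] = np.where(use_lower[idx], other, direct)
        start = stop
    return lower, upper

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ConfigError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


class DEResults:
    """Per-gene differential-expression results of one contrast.

    Wraps a DataFrame (index = gene IDs) with columns logFC, logCPM,
    PValue and FDR.
    """

    def __init__(self, frame: pd.DataFrame, control: str, treatment: str,
                 dispersion: float) -> None:
        self.frame = frame[RESULT_COLUMNS].copy()
        self.control = control
        self.treatment = treatment
        self.dispersion = dispersion

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    def count_degs(self, fdr_threshold: float = 0.01) -> dict:
        return count_degs(self, fdr_threshold)

    def summary(self, fdr_threshold: float = 0.01) -> str:
        c = self.count_degs(fdr_threshold)
        lines = [
            f"NB exact test: {self.treatment} vs {self.control}",
            f"  genes tested:      {len(self.frame)}",
            f"  common dispersion: {self.dispersion:.4g}",
            f"  DEGs (FDR<{fdr_threshold:g}):  {c['total']} "
            f"({c['up']} up, {c['down']} down)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


class NBExactTest:
    """Exact NB test of one treatment condition against the control.

    Parameters
    ----------
    counts
        The full count matrix; only the two conditions of the contrast
        are used.
    control, treatment
        Condition labels.
    dispersion
        Common NB dispersion phi; estimated from the contrast's
        replicates when None.
    """

    def __init__(self, counts: CountMatrix, control: str, treatment: str,
                 dispersion: float | DispersionEstimate | None = None,
                 norm_factors: pd.Series | None = None) -> None:
        for cond in (control, treatment):
            if cond not in set(counts.conditions):
                raise ConfigError(f"unknown condition label {cond!r}")
        self.data = counts.subset_conditions([control, treatment])
        self.control = control
        self.treatment = treatment
        if isinstance(dispersion, DispersionEstimate):
            dispersion = dispersion.common
        if dispersion is not None and not (np.isfinite(dispersion) and dispersion >= 0):
            raise ConfigError("dispersion must be finite and >= 0")
        self.dispersion = dispersion
        if norm_factors is not None:
            norm_factors = pd.Series(norm_factors, index=self.data.sample_ids).astype(float)
        self.norm_factors = norm_factors

    def fit(self) -> DEResults:
        phi = self.dispersion
        if phi is None:
            phi = estimate_common_dispersion(
                self.data, (self.control, self.treatment), self.norm_factors
            ).common

        cm = self.data
        cols_c = _group_cols(cm, self.control)
        cols_t = _group_cols(cm, self.treatment)
        pseudo, eff, _ = _pseudo_counts(cm, self.norm_factors)
        raw = cm.counts.to_numpy(dtype=float)
        eff_np = eff.to_numpy()

        # equalised group sums, rounded for the discrete conditional test
        s_c = np.rint(pseudo[:, cols_c].sum(axis=1)).astype(np.int64)
        s_t = np.rint(pseudo[:, cols_t].sum(axis=1)).astype(np.int64)
        z = s_c + s_t
        n_c, n_t = cols_c.size, cols_t.size

        p = np.ones(cm.n_genes)
        nz = z > 0
        if phi < 1e-10:
            # Poisson limit: conditional distribution of the treatment sum is binomial
            frac = n_t / (n_c + n_t)
            lower = binom.cdf(s_t[nz], z[nz], frac)
            upper = binom.sf(s_t[nz] - 1, z[nz], frac)
        else:
            a, b = n_t / phi, n_c / phi
            lower, upper = _betabinom_tails(s_t[nz], z[nz], a, b)
        p[nz] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))

        lib_c = eff_np[cols_c].sum()
        lib_t = eff_np[cols_t].sum()
        sum_c = raw[:, cols_c].sum(axis=1)
        sum_t = raw[:, cols_t].sum(axis=1)
        logfc = np.log2((sum_t + 0.5) / (sum_c + 0.5) * (lib_c / lib_t))
        cpm = (raw + 0.5) / (eff_np + 1.0)[None, :] * 1e6
        logcpm = np.log2(cpm.mean(axis=1))

        frame = pd.DataFrame(
            {"logFC": logfc, "logCPM": logcpm, "PValue": p, "FDR": bh_fdr(p)},
            index=cm.gene_ids,
        )
        return DEResults(frame, self.control, self.treatment, phi)


def nb_exact_test(
    counts: CountMatrix, control: str, treatment: str,
    dispersion: float | DispersionEstimate | None = None,
    norm_factors: pd.Series | None = None,
) -> DEResults:
    """Functional shorthand for ``NBExactTest(...).fit()``."""
    return NBExactTest(counts, control, treatment, dispersion, norm_factors).fit()


def count_degs(de: DEResults, fdr_threshold: float = 0.01) -> dict:
    """Up/down/total DEG counts at a strict FDR threshold."""
    f = de.frame
    sig = f["FDR"] < fdr_threshold
    up = int((sig & (f["logFC"] > 0)).sum())
    down = int((sig & (f["logFC"] < 0)).sum())
    return {"up": up, "down": down, "total": up + down}
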