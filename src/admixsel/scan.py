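"""Admixture-constrained likelihood-ratio test for selection, with calibration.

The test compares, per variant, an alternative model in which each of the
A+B populations has a free allele frequency (MLE f_i = x_i/N_i) against a
null in which the population frequencies are constrained to the image of the
genome-wide admixture proportions: f = M q, where M is the (A+B) x k
admixture matrix and q the variant's (unknown) frequencies in the k source
populations.  Twice the log-likelihood difference is asymptotically
chi-squared with A+B-k degrees of freedom.  Residual inflation from genetic
drift (which the binomial sampling model ignores) is removed either by
genomic control or by fitting a gamma null to the observed statistics.

The null maximization is a small box-constrained concave problem; it is
solved by damped projected Newton iterations compiled with numba so that the
permutation machinery elsewhere in the package can afford millions of fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .popdata import AdmixtureMatrix, PopulationCounts, SourceFrequencies, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "CalibrationReport",
    "NumericalError",
    "loglik_alt",
    "fit_null",
    "lrt",
    "lrt_batch",
    "calibrate",
    "bh_qvalues",
    "ld_companion_filter",
    "hla_density_correct",
    "replication_test",
]

GENOME_WIDE_ALPHA = 5e-8

_FEPS = 1e-12


class NumericalError(RuntimeError):
    """An optimizer or sampler failed to converge."""


@dataclass(frozen=True)
class ScanResult:
    """Per-variant outcome of the likelihood-ratio selection test."""

    variant_id: str
    ell1: float
    ell0: float
    stat: float
    df: int
    p_raw: float
    q_hat: SourceFrequencies
    p_adj: Optional[float] = None
    monomorphic: bool = False


@dataclass(frozen=True)
class CalibrationReport:
    """How a batch of test statistics was re-calibrated."""

    lambda_gc: float
    method: str  # "genomic_control" | "gamma_fit"
    gamma_shape: Optional[float] = None
    gamma_scale: Optional[float] = None

    def __post_init__(self):
        if self.lambda_gc <= 0:
            raise ValidationError("lambda_gc must be positive")
        has_gamma = self.gamma_shape is not None and self.gamma_scale is not None
        if (self.method == "gamma_fit") != has_gamma:
            raise ValidationError("gamma parameters present iff method == gamma_fit")


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _binom_ll(f, x, N):
    # x log f + (N-x) log(1-f) with the 0*log0 = 0 convention; the floors
    # only bite when a positive count meets a boundary frequency, keeping
    # the optimizer's objective finite.
    ll = 0.0
    for i in range(x.shape[0]):
        if N[i] == 0:
            continue
        fi = f[i]
        if x[i] > 0:
            ll += x[i] * np.log(max(fi, _FEPS))
        if N[i] - x[i] > 0:
            ll += (N[i] - x[i]) * np.log(max(1.0 - fi, _FEPS))
    return ll


@njit(cache=True)
def _ell0_of(q, x, N, M):
    f = M @ q
    return _binom_ll(f, x, N)


@njit(cache=True)
def _solve_spd(H, g, d):
    """d = H^-1 g for the small SPD curvature matrix (Cramer for k <= 3)."""
    k = H.shape[0]
    if k == 1:
        d[0] = g[0] / H[0, 0]
    elif k == 2:
        det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
        d[0] = (g[0] * H[1, 1] - g[1] * H[0, 1]) / det
        d[1] = (g[1] * H[0, 0] - g[0] * H[1, 0]) / det
    elif k == 3:
        a, b, c = H[0, 0], H[0, 1], H[0, 2]
        e, f_, h = H[1, 1], H[1, 2], H[2, 2]
        det = a * (e * h - f_ * f_) - b * (b * h - f_ * c) + c * (b * f_ - e * c)
        d[0] = (
            g[0] * (e * h - f_ * f_) - b * (g[1] * h - f_ * g[2]) + c * (g[1] * f_ - e * g[2])
        ) / det
        d[1] = (
            a * (g[1] * h - f_ * g[2]) - g[0] * (b * h - f_ * c) + c * (b * g[2] - g[1] * c)
        ) / det
        d[2] = (
            a * (e * g[2] - g[1] * f_) - b * (b * g[2] - g[1] * c) + g[0] * (b * f_ - e * c)
        ) / det
    else:
        d[:] = np.linalg.solve(H, g)


@njit(cache=True)
def _fit_from(q0, x, N, M, tol, maxit):
    """Damped projected-Newton ascent of the concave null log-likelihood."""
    k = M.shape[1]
    n = M.shape[0]
    q = q0.copy()
    ll = _ell0_of(q, x, N, M)
    g = np.zeros(k)
    H = np.zeros((k, k))
    d = np.zeros(k)
    for _ in range(maxit):
        f = M @ q
        for j in range(k):
            g[j] = 0.0
            for l in range(k):
                H[j, l] = 0.0
        for i in range(n):
            if N[i] == 0:
                continue
            fi = min(max(f[i], _FEPS), 1.0 - _FEPS)
            w1 = x[i] / fi - (N[i] - x[i]) / (1.0 - fi)
            w2 = x[i] / (fi * fi) + (N[i] - x[i]) / ((1.0 - fi) * (1.0 - fi))
            for j in range(k):
                g[j] += M[i, j] * w1
                for l in range(j + 1):
                    H[j, l] += M[i, j] * M[i, l] * w2
        for j in range(k):
            for l in range(j):
                H[l, j] = H[j, l]
        # projected-gradient convergence check on the box [0,1]^k
        pgnorm = 0.0
        for j in range(k):
            gj = g[j]
            if q[j] <= 0.0 and gj < 0.0:
                gj = 0.0
            elif q[j] >= 1.0 and gj > 0.0:
                gj = 0.0
            pgnorm += gj * gj
        if np.sqrt(pgnorm) < tol:
            return q, ll, True
        # active-set reduction: freeze coordinates pinned at a bound whose
        # gradient points outward, and take the Newton step on the rest
        nfree = 0
        for j in range(k):
            active = (q[j] <= 0.0 and g[j] < 0.0) or (q[j] >= 1.0 and g[j] > 0.0)
            if active:
                g[j] = 0.0
                for l in range(k):
                    H[j, l] = 0.0
                    H[l, j] = 0.0
                H[j, j] = 1.0
            else:
                nfree += 1
        if nfree == 0:
            return q, ll, True
        ridge = 1e-10 + 1e-10 * np.trace(H)
        for j in range(k):
            H[j, j] += ridge
        _solve_spd(H, g, d)
        step = 1.0
        improved = False
        for _bt in range(60):
            qn = np.minimum(np.maximum(q + step * d, 0.0), 1.0)
            lln = _ell0_of(qn, x, N, M)
            if lln > ll + 1e-14:
                q, ll = qn, lln
                improved = True
                break
            step *= 0.5
        if not improved:
            # Newton direction exhausted; fall back to a projected-gradient probe
            step = 1.0 / (1.0 + np.sqrt(pgnorm))
            for _bt in range(60):
                qn = np.minimum(np.maximum(q + step * g, 0.0), 1.0)
                lln = _ell0_of(qn, x, N, M)
                if lln > ll + 1e-14:
                    q, ll = qn, lln
                    improved = True
                    break
                step *= 0.5
            if not improved:
                return q, ll, True  # stationary up to floating point
    return q, ll, False


@njit(cache=True)
def _fit_null_core(x, N, M, corners, tol, maxit):
    k = M.shape[1]
    xs = 0.0
    ns = 0.0
    for i in range(len(x)):
        xs += x[i]
        ns += N[i]
    pooled = xs / ns if ns > 0 else 0.5
    best_q = np.full(k, pooled)
    best_q, best_ll, _ = _fit_from(best_q, x, N, M, tol, maxit)
    for c in range(corners.shape[0]):
        q0 = np.minimum(np.maximum(corners[c] * 0.98 + 0.01, 0.0), 1.0)
        q, ll, _ = _fit_from(q0, x, N, M, tol, maxit)
        if ll > best_ll + 1e-12:
            best_ll = ll
            best_q = q
    return best_q, best_ll


@njit(cache=True)
def _lrt_batch_core(X, Ns, M, tol, maxit):
    # single pooled start per variant: the objective is concave, so the
    # projected Newton ascent lands on the global maximum from anywhere
    V = X.shape[0]
    k = M.shape[1]
    stats_out = np.empty(V)
    ell1s = np.empty(V)
    ell0s = np.empty(V)
    Q = np.empty((V, k))
    q0 = np.empty(k)
    for v in range(V):
        x = X[v]
        N = Ns[v]
        f1 = np.empty(len(x))
        xs = 0.0
        ns = 0.0
        for i in range(len(x)):
            f1[i] = x[i] / N[i] if N[i] > 0 else 0.0
            xs += x[i]
            ns += N[i]
        e1 = _binom_ll(f1, x, N)
        pooled = min(max(xs / ns if ns > 0 else 0.5, 1e-3), 1.0 - 1e-3)
        for j in range(k):
            q0[j] = pooled
        q, e0, _ = _fit_from(q0, x, N, M, tol, maxit)
        ell1s[v] = e1
        ell0s[v] = e0
        Q[v] = q
        s = 2.0 * (e1 - e0)
        stats_out[v] = s if s > 0.0 else 0.0
    return stats_out, ell1s, ell0s, Q


def _corner_starts(k: int) -> np.ndarray:
    """Vertex starts of the unit box (capped at 16 for large k)."""
    if k <= 4:
        grid = np.indices((2,) * k).reshape(k, -1).T.astype(float)
        return grid
    rng = np.random.default_rng(0)
    return rng.integers(0, 2, size=(16, k)).astype(float)


# ---------------------------------------------------------------------------
# public per-variant operations


def loglik_alt(counts: PopulationCounts) -> float:
    """Unconstrained log-likelihood: each population at its own MLE x_i/N_i.

    Populations with no called alleles are skipped; monomorphic terms use
    the 0*log(0) = 0 convention.
    """
    N = counts.N
    x = counts.x
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(N > 0, x / np.maximum(N, 1), 0.0)
    return float(_binom_ll(f.astype(float), x.astype(float), N.astype(float)))


def fit_null(
    counts: PopulationCounts,
    M: AdmixtureMatrix,
    tol: float = 1e-8,
    maxit: int = 200,
):
    """Maximize the constrained likelihood over source frequencies q in [0,1]^k.

    Expected population frequencies are f = M q.  The objective is concave,
    and is climbed by projected Newton from the pooled-frequency start plus
    box-corner starts.  Returns ``(SourceFrequencies, ell0)``.
    """
    if M.n_populations != counts.n_populations:
        raise ValidationError(
            f"variant {counts.variant_id}: counts have {counts.n_populations} "
            f"populations but M has {M.n_populations} rows"
        )
    x = counts.x.astype(float)
    N = counts.N.astype(float)
    q, ell0 = _fit_null_core(x, N, M.M, _corner_starts(M.k), tol, maxit)
    if not np.all(np.isfinite(q)):
        raise NumericalError(
            f"variant {counts.variant_id}: null fit produced non-finite q"
        )
    return SourceFrequencies(q=np.clip(q, 0.0, 1.0)), float(ell0)


def lrt(counts: PopulationCounts, M: AdmixtureMatrix) -> ScanResult:
    """Likelihood-ratio test of free vs admixture-constrained frequencies.

    stat = 2(l1 - l0) (clipped below at 0) is referred to a chi-squared
    distribution with A+B-k degrees of freedom.
    """
    df = M.n_populations - M.k
    if df < 1:
        raise ValidationError(
            f"k={M.k} sources with {M.n_populations} populations leaves no "
            "degrees of freedom for the test (need k <= A+B-1)"
        )
    ell1 = loglik_alt(counts)
    q_hat, ell0 = fit_null(counts, M)
    stat = max(2.0 * (ell1 - ell0), 0.0)
    pooled_mono = counts.x.sum() == 0 or counts.x.sum() == counts.N.sum()
    return ScanResult(
        variant_id=counts.variant_id,
        ell1=ell1,
        ell0=ell0,
        stat=stat,
        df=df,
        p_raw=float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0,
        q_hat=q_hat,
        monomorphic=bool(pooled_mono),
    )


def lrt_batch(X: np.ndarray, Ns: np.ndarray, M: AdmixtureMatrix):
    """Vectorized LRT over a (V, A+B) array of counts.

    Returns ``(stats, ell1, ell0, q_hat)`` arrays; p-values are left to the
    calibration step.
    """
    X = np.ascontiguousarray(X, dtype=float)
    Ns = np.ascontiguousarray(Ns, dtype=float)
    if X.shape != Ns.shape or X.shape[1] != M.n_populations:
        raise ValidationError("counts arrays and admixture matrix disagree in shape")
    return _lrt_batch_core(X, Ns, M.M, 1e-7, 200)


# ---------------------------------------------------------------------------
# calibration


def calibrate(stats_vec: np.ndarray, df: int, method: str = "genomic_control"):
    """Re-calibrate LRT statistics for drift-driven inflation.

    genomic_control
        lambda = median(stats) / median(chi2_df); adjusted p-values come from
        chi2_df applied to stat / lambda.  Requires >= 100 statistics.
    gamma_fit
        Maximum-likelihood gamma fitted to the statistics; adjusted p-values
        are its upper tail.  Requires >= 1000 statistics.  (chi2_df is the
        special case shape = df/2, scale = 2.)

    Returns ``(CalibrationReport, p_adj)``.
    """
    stats_vec = np.asarray(stats_vec, dtype=float)
    if np.all(stats_vec == stats_vec[0]):
        raise ValidationError("degenerate (all-equal) statistics cannot be calibrated")
    if method == "genomic_control":
        if len(stats_vec) < 100:
            raise ValidationError("genomic control needs >= 100 statistics")
        lam = float(np.median(stats_vec) / sps.chi2.median(df))
        p_adj = sps.chi2.sf(stats_vec / lam, df)
        return CalibrationReport(lambda_gc=lam, method="genomic_control"), p_adj
    if method == "gamma_fit":
        if len(stats_vec) < 1000:
            raise ValidationError("gamma fit needs >= 1000 statistics")
        positive = stats_vec[stats_vec > 0]
        shape, _, scale = sps.gamma.fit(positive, floc=0.0)
        lam = float(np.median(stats_vec) / sps.chi2.median(df))
        p_adj = sps.gamma.sf(stats_vec, shape, loc=0.0, scale=scale)
        return (
            CalibrationReport(
                lambda_gc=lam,
                method="gamma_fit",
                gamma_shape=float(shape),
                gamma_scale=float(scale),
            ),
            p_adj,
        )
    raise ValueError(f"unknown calibration method {method!r}")


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values over the full set of tested variants."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# filtering, HLA correction, replication


def ld_companion_filter(
    results: pd.DataFrame,
    ld: pd.DataFrame,
    fdr_q: float = 0.1,
    window: int = 200_000,
    min_companions: int = 1,
    r2_min: float = 0.5,
) -> pd.DataFrame:
    """Require FDR-passing variants to have LD companions that also pass.

    ``results`` needs columns chrom, pos, id and p_adj (q_value is computed
    here if absent).  ``ld`` has columns id1, id2, r2; absent pairs count as
    r2 = 0.  A variant passes iff its own BH-FDR < ``fdr_q`` and at least
    ``min_companions`` other variants within +-``window`` bp on the same
    chromosome have r2 > ``r2_min`` with it and themselves have FDR < fdr_q.
    """
    out = results.copy()
    if "q_value" not in out.columns:
        out["q_value"] = bh_qvalues(out["p_adj"].to_numpy())
    partners: dict = {}
    for row in ld.itertuples(index=False):
        if row.r2 > r2_min:
            partners.setdefault(row.id1, set()).add(row.id2)
            partners.setdefault(row.id2, set()).add(row.id1)
    passing = out[out["q_value"] < fdr_q]
    pass_ids = set(passing["id"])
    pos_of = dict(zip(out["id"], zip(out["chrom"], out["pos"])))
    n_missing_ld = 0
    n_comp = np.zeros(len(out), dtype=int)
    flags = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        if row.q_value >= fdr_q:
            continue
        mates = partners.get(row.id)
        if mates is None:
            n_missing_ld += 1
            continue
        cnt = 0
        for mate in mates:
            if mate == row.id or mate not in pass_ids or mate not in pos_of:
                continue
            mchrom, mpos = pos_of[mate]
            if mchrom == row.chrom and abs(mpos - row.pos) <= window:
                cnt += 1
        n_comp[i] = cnt
        flags[i] = cnt >= min_companions
    if n_missing_ld:
        logger.info(
            "LD-companion filter: %d FDR-passing variants had no LD entries "
            "(treated as r2=0)",
            n_missing_ld,
        )
    out["n_companions"] = n_comp
    out["pass_filter"] = flags
    logger.info(
        "LD-companion filter: %d/%d FDR<%g variants retained",
        int(flags.sum()),
        len(passing),
        fdr_q,
    )
    return out


def hla_density_correct(
    results: pd.DataFrame,
    region_start: int,
    region_end: int,
    window: int = 50_000,
):
    """SNP-density correction for dense regions such as the MHC.

    Windows of ``window`` bp tile the region from its start (1-based
    inclusive input coordinates); each p-value is multiplied by the number
    of SNPs in its window (clipped at 1).  The region-wide significance
    threshold corrects for the number of non-empty windows: 0.05 / n_windows.

    Returns ``(DataFrame with p_corrected and window_index, threshold)``.
    """
    out = results.copy()
    if len(out) == 0:
        return out.assign(p_corrected=[], window_index=[]), np.nan
    start0 = region_start - 1  # 0-based half-open internally
    pos0 = out["pos"].to_numpy() - 1
    if np.any(pos0 < start0) or np.any(out["pos"].to_numpy() > region_end):
        raise ValidationError("variant outside the stated region")
    widx = (pos0 - start0) // window
    counts = pd.Series(widx).value_counts()
    per_variant = counts.loc[widx].to_numpy()
    pcol = "p_adj" if "p_adj" in out.columns else "p_raw"
    out["window_index"] = widx
    out["p_corrected"] = np.minimum(out[pcol].to_numpy() * per_variant, 1.0)
    threshold = 0.05 / len(counts)
    return out, threshold


def replication_test(
    leads: pd.DataFrame,
    other: pd.DataFrame,
    window: int = 1_000_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test whether one region's lead hits replicate in another region's scan.

    Lead-level: the lead variant's p-value in the other region against a
    Bonferroni threshold alpha / n_leads (NA if the variant was not tested
    there).  Locus-level: the minimum p within +-``window`` bp of the lead
    against alpha / (number of SNPs tested in that window).
    """
    n_leads = len(leads)
    pcol = "p_adj" if "p_adj" in other.columns else "p_raw"
    p_other = dict(zip(other["id"], other[pcol]))
    rows = []
    for lead in leads.itertuples(index=False):
        p_lead = p_other.get(lead.id, np.nan)
        lead_thresh = alpha / n_leads
        in_win = other[
            (other["chrom"] == lead.chrom)
            & (np.abs(other["pos"] - lead.pos) <= window)
        ]
        n_win = len(in_win)
        min_p = float(in_win[pcol].min()) if n_win else np.nan
        rows.append(
            {
                "id": lead.id,
                "chrom": lead.chrom,
                "pos": lead.pos,
                "p_other": p_lead,
                "lead_threshold": lead_thresh,
                "lead_replicates": (
                    bool(p_lead < lead_thresh) if np.isfinite(p_lead) else None
                ),
                "n_snps_window": n_win,
                "min_p_window": min_p,
                "locus_threshold": alpha / n_win if n_win else np.nan,
                "locus_replicates": bool(min_p < alpha / n_win) if n_win else None,
            }
        )
    return pd.DataFrame(rows)
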