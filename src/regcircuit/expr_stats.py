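"""Companion expression statistics.

Implements the quantitative toolkit around the network analysis:

* efficiency-corrected relative expression of qPCR data (Pfaffl ratio,
  ``E_target**dCt_target / E_ref**dCt_ref`` with dCt = control-minus-treated
  mean Ct, so a ratio above 1 means up-regulation in the treated group);
* the pair-wise fixed reallocation randomisation test: samples (their
  target and reference Ct jointly — "fixed") are reallocated between the
  two groups, preserving group sizes, and the two-sided p-value is the
  proportion of reallocations whose |log ratio| reaches the observed one;
* Pearson correlation matrices with 95% CIs from the Fisher
  variance-stabilising transform (Gaussian assumption), significance =
  CI excludes zero;
* grand-mean log centering of per-group means (heat-map transform);
* hypergeometric gene-set enrichment with Benjamini-Hochberg adjustment;
* genotype-proportion tests (Fisher exact for 2x2, chi-square for 2xk).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GeneSet, ValidationError


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected expression ratio.

    ``dct`` values are control-minus-treated differences of mean Ct;
    efficiencies are per-primer amplification factors (2 for perfect
    doubling).  Non-positive efficiencies are rejected.
    """
    if e_target <= 0 or e_ref <= 0:
        raise ValidationError("amplification efficiencies must be positive")
    return e_target ** dct_target / e_ref ** dct_ref


@dataclass(frozen=True)
class ReallocationResult:
    ratio: float
    p: float
    n_reallocations: int
    exhaustive: bool


def _group_ratio(ct_t: np.ndarray, ct_r: np.ndarray, mask_control: np.ndarray,
                 e_target: float, e_ref: float) -> float:
    dct_t = ct_t[mask_control].mean() - ct_t[~mask_control].mean()
    dct_r = ct_r[mask_control].mean() - ct_r[~mask_control].mean()
    return pfaffl_ratio(e_target, dct_t, e_ref, dct_r)


def reallocation_test(
    ct_target: Sequence[float],
    ct_ref: Sequence[float],
    groups: Sequence[str],
    control: str,
    treated: str,
    e_target: float = 2.0,
    e_ref: float = 2.0,
    n_perm: int = 2000,
    rng_seed: Optional[int] = None,
) -> ReallocationResult:
    """Fixed reallocation randomisation test for one gene against a reference.

    ``ct_target``/``ct_ref`` are per-sample Ct values (aligned), ``groups``
    labels each sample.  The observed statistic is the Pfaffl ratio on group
    mean Cts; the null reallocates samples (target and reference Ct moving
    together) between the groups.  All C(n, n_control) distinct reallocations
    are enumerated when that count does not exceed ``n_perm``; otherwise
    ``n_perm`` random reallocations are drawn (seeded) and the observed
    allocation is included in the numerator and denominator.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_ref, dtype=float)
    grp = np.asarray(groups)
    if not (len(ct_t) == len(ct_r) == len(grp)):
        raise ValidationError("ct_target, ct_ref and groups must be aligned")
    keep = np.isin(grp, [control, treated])
    ct_t, ct_r, grp = ct_t[keep], ct_r[keep], grp[keep]
    n_ctrl = int((grp == control).sum())
    n_trt = int((grp == treated).sum())
    if n_ctrl < 2 or n_trt < 2:
        raise ValidationError("each group needs at least two samples")
    n = n_ctrl + n_trt

    obs_mask = grp == control
    ratio = _group_ratio(ct_t, ct_r, obs_mask, e_target, e_ref)
    obs_stat = abs(np.log(ratio))
    tol = 1e-12

    n_distinct = comb(n, n_ctrl)
    if n_distinct <= n_perm:
        hits = 0
        for ctrl_idx in combinations(range(n), n_ctrl):
            mask = np.zeros(n, dtype=bool)
            mask[list(ctrl_idx)] = True
            stat = abs(np.log(_group_ratio(ct_t, ct_r, mask, e_target, e_ref)))
            if stat >= obs_stat - tol:
                hits += 1
        return ReallocationResult(ratio=ratio, p=hits / n_distinct,
                                  n_reallocations=n_distinct, exhaustive=True)

    rng = np.random.default_rng(rng_seed)
    hits = 1  # the observed allocation counts
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_ctrl]] = True
        stat = abs(np.log(_group_ratio(ct_t, ct_r, mask, e_target, e_ref)))
        if stat >= obs_stat - tol:
            hits += 1
    return ReallocationResult(ratio=ratio, p=hits / (n_perm + 1),
                              n_reallocations=n_perm, exhaustive=False)


# ---------------------------------------------------------------------------
# Correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with Gaussian 95% CIs.

    All frames are gene x gene; ``valid`` is False where a coefficient is
    undefined (zero variance or fewer than 4 complete pairs).
    """

    r: pd.DataFrame
    lo: pd.DataFrame
    hi: pd.DataFrame
    n: pd.DataFrame
    significant: pd.DataFrame
    valid: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        genes = list(self.r.index)
        for a, b in combinations(genes, 2):
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "r": self.r.loc[a, b],
                    "ci_lo": self.lo.loc[a, b],
                    "ci_hi": self.hi.loc[a, b],
                    "n": self.n.loc[a, b],
                    "significant": bool(self.significant.loc[a, b]),
                    "valid": bool(self.valid.loc[a, b]),
                }
            )
        return pd.DataFrame(rows)


def pearson_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """CI for a Pearson coefficient via z = atanh(r) +/- z_crit/sqrt(n-3)."""
    if n < 4:
        raise ValidationError("need n >= 4 for a Fisher-z confidence interval")
    if abs(r) >= 1.0:
        return (r, r)
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    half = zcrit / np.sqrt(n - 3)
    z = np.arctanh(r)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlation_matrix(values: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation of a gene x sample table.

    Requires at least 4 samples overall; a pair with fewer than 4 complete
    observations, or a zero-variance gene, yields an invalid entry (NaN r,
    not significant).  The diagonal is exactly 1 with a degenerate CI.
    """
    if values.shape[1] < 4:
        raise ValidationError("need at least 4 samples (columns)")
    genes = list(values.index)
    m = len(genes)
    r = np.full((m, m), np.nan)
    lo = np.full((m, m), np.nan)
    hi = np.full((m, m), np.nan)
    nmat = np.zeros((m, m), dtype=int)
    sig = np.zeros((m, m), dtype=bool)
    valid = np.zeros((m, m), dtype=bool)
    x = values.to_numpy(dtype=float)
    for i in range(m):
        r[i, i], lo[i, i], hi[i, i] = 1.0, 1.0, 1.0
        nmat[i, i] = int(np.isfinite(x[i]).sum())
        sig[i, i] = True
        valid[i, i] = True
        for j in range(i + 1, m):
            ok = np.isfinite(x[i]) & np.isfinite(x[j])
            nn = int(ok.sum())
            nmat[i, j] = nmat[j, i] = nn
            if nn < 4:
                continue
            xi, xj = x[i, ok], x[j, ok]
            if xi.std() == 0 or xj.std() == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            l, h = pearson_ci(rij, nn)
            s = l > 0 or h < 0
            r[i, j] = r[j, i] = rij
            lo[i, j] = lo[j, i] = l
            hi[i, j] = hi[j, i] = h
            sig[i, j] = sig[j, i] = s
            valid[i, j] = valid[j, i] = True

    def df(a, dtype=None):
        return pd.DataFrame(a, index=genes, columns=genes)

    return CorrelationMatrix(
        r=df(r), lo=df(lo), hi=df(hi), n=df(nmat), significant=df(sig), valid=df(valid)
    )


# ---------------------------------------------------------------------------
# Heat-map transform
# ---------------------------------------------------------------------------

def grand_mean_center(
    group_means: pd.DataFrame, pseudocount: float = 1.0, base: float = 2.0
) -> pd.DataFrame:
    """Log-transform per-group means and center each gene on its grand mean.

    ``out[g, grp] = log_base(mean + pc) - mean_over_groups(log_base(mean + pc))``;
    row sums are zero by construction.
    """
    if (group_means.to_numpy(dtype=float) < 0).any():
        raise ValidationError("group means must be non-negative")
    logged = np.log(group_means.astype(float) + pseudocount) / np.log(base)
    return logged.sub(logged.mean(axis=1), axis=0)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    overlap: int
    expected: float
    fold: float
    p: float


def enrichment_test(hits: GeneSet, category: GeneSet, background: GeneSet) -> EnrichmentResult:
    """Upper hypergeometric tail for the hits/category overlap.

    ``p = P(X >= overlap)`` with X ~ Hypergeom(|background|, |category|,
    |hits|); fold enrichment is observed over expected overlap.
    """
    if len(background) == 0:
        raise ValidationError("background gene set is empty")
    if not hits.members <= background.members:
        raise ValidationError("hits must be a subset of the background")
    if not category.members <= background.members:
        raise ValidationError("category must be a subset of the background")
    m, k_cat, n_hit = len(background), len(category), len(hits)
    overlap = len(hits.members & category.members)
    expected = n_hit * k_cat / m
    fold = overlap / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(overlap - 1, m, k_cat, n_hit))
    return EnrichmentResult(category=category.name, overlap=overlap,
                            expected=expected, fold=fold, p=min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Genotype proportions
# ---------------------------------------------------------------------------

def proportion_test(table) -> float:
    """Two-sided test of homogeneity for a 2x2 or 2xk count table.

    2x2 tables use Fisher's exact test (two-sided, summed point
    probabilities at or below the observed table); wider 2xk tables use the
    Pearson chi-square test with k-1 degrees of freedom (no continuity
    correction).
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValidationError("expected a 2xk table with k >= 2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise ValidationError("counts must be non-negative integers")
        t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("table has an all-zero margin")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    return float(stats.chi2_contingency(t, correction=False)[1])
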