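"""Per-locus and hierarchical F-statistics and the runs test.

F_ST is the Weir–Cockerham theta estimator built from among/within-
population allele-frequency variance components; the same estimator is
applied to observed panels and to coalescent-simulated samples so that the
outlier comparison is internally consistent. H_BP is the expected
heterozygosity of the unweighted mean of population allele frequencies,
the quantity used to condition the F_ST null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MISSING, GenotypePanel


class MonomorphicLocusError(ValueError):
    """The locus carries a single allele in the total sample."""


def _theta_components(p, n, h):
    """Weir–Cockerham variance components (a, b, c) for one biallelic locus.

    Parameters are per-population arrays: allele frequency ``p``, diploid
    sample size ``n`` and observed heterozygote proportion ``h``.
    Populations with n == 0 are dropped by the callers.
    """
    r = len(p)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def locus_fst(genotypes: np.ndarray, pops: np.ndarray) -> float:
    """Weir–Cockerham theta at a single SNP.

    ``genotypes`` is a vector of diploid dosages (0/1/2, MISSING dropped),
    ``pops`` the parallel population labels. Raises on a single effective
    population or a monomorphic locus.
    """
    genotypes = np.asarray(genotypes)
    pops = np.asarray(pops)
    called = genotypes != MISSING
    genotypes, pops = genotypes[called], pops[called]
    labels = pd.unique(pops)
    p, n, h = [], [], []
    for lab in labels:
        g = genotypes[pops == lab]
        if len(g) == 0:
            continue
        n.append(len(g))
        p.append(g.sum() / (2.0 * len(g)))
        h.append((g == 1).mean())
    if len(n) < 2:
        raise ValueError("locus_fst requires >= 2 populations with data")
    p, n, h = map(np.asarray, (p, n, h))
    if genotypes.sum() == 0 or genotypes.sum() == 2 * len(genotypes):
        raise MonomorphicLocusError("monomorphic locus: theta undefined")
    a, b, c = _theta_components(p.astype(float), n.astype(float), h.astype(float))
    return float(a / (a + b + c))


def panel_fst(panel: GenotypePanel) -> np.ndarray:
    """Vectorized Weir–Cockerham theta for every SNP of a panel.

    Monomorphic or single-population SNPs get NaN. Agrees with
    :func:`locus_fst` locus by locus.
    """
    pops = panel.populations
    g = panel.genotypes
    called = g != MISSING
    n_snps = panel.n_snps
    P = np.zeros((n_snps, len(pops)))
    N = np.zeros((n_snps, len(pops)))
    H = np.zeros((n_snps, len(pops)))
    for k, cols in enumerate(panel.pop_indices().values()):
        sub = g[:, cols]
        c = called[:, cols]
        n = c.sum(axis=1)
        N[:, k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            P[:, k] = np.where(n > 0, np.where(c, sub, 0).sum(axis=1) / (2.0 * n), 0.0)
            H[:, k] = np.where(n > 0, ((sub == 1) & c).sum(axis=1) / np.maximum(n, 1), 0.0)
    return _theta_vectorized(P, N, H)


def theta_components_vectorized(P, N, H):
    """Row-wise Weir–Cockerham components: returns (a, a+b+c) per locus.

    NaN where theta is undefined (monomorphic or < 2 populations). The
    multilocus ratio-of-sums estimator is nansum(a)/nansum(a+b+c).
    """
    present = N > 0
    r = present.sum(axis=1).astype(float)
    n_tot = N.sum(axis=1)
    nbar = np.where(r > 0, n_tot / np.maximum(r, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (N ** 2).sum(axis=1) / (r * nbar)) / (r - 1)
        pbar = (N * P).sum(axis=1) / (r * nbar)
        s2 = (N * (P - pbar[:, None]) ** 2 * present).sum(axis=1) / ((r - 1) * nbar)
        hbar = (N * H).sum(axis=1) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    dose = (2 * N * P).sum(axis=1)
    poly = (dose > 1e-9) & (np.abs(dose - 2 * n_tot) > 1e-9) & (r >= 2)
    a = np.where(poly, a, np.nan)
    abc = np.where(poly, a + b + c, np.nan)
    return a, abc


def multilocus_fst(P, N, H) -> float:
    """Ratio-of-sums Weir–Cockerham theta over loci (the standard
    multilocus estimator, and the quantity matched by island-model
    expectations)."""
    a, abc = theta_components_vectorized(P, N, H)
    return float(np.nansum(a) / np.nansum(abc))


def _theta_vectorized(P, N, H):
    """Row-wise theta from per-population frequency/size/het matrices."""
    present = N > 0
    r = present.sum(axis=1).astype(float)
    n_tot = N.sum(axis=1)
    nbar = np.where(r > 0, n_tot / np.maximum(r, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (N ** 2).sum(axis=1) / (r * nbar)) / (r - 1)
        pbar = (N * P).sum(axis=1) / (r * nbar)
        s2 = (N * (P - pbar[:, None]) ** 2 * present).sum(axis=1) / ((r - 1) * nbar)
        hbar = (N * H).sum(axis=1) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        theta = a / (a + b + c)
    dose = (2 * N * P).sum(axis=1)
    poly = (dose > 1e-9) & (np.abs(dose - 2 * n_tot) > 1e-9)
    theta[~poly | (r < 2)] = np.nan
    return theta


def h_bp(freqs: np.ndarray) -> float | np.ndarray:
    """Between-population heterozygosity 2·p̄(1−p̄).

    ``p̄`` is the unweighted mean of per-population allele frequencies;
    NaN frequencies (populations without data) are ignored. Accepts a
    vector (one locus) or a matrix (loci × populations).
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim == 1:
        if np.isnan(freqs).all():
            raise ValueError("h_bp: no population with a defined frequency")
        pbar = np.nanmean(freqs)
        return float(2.0 * pbar * (1.0 - pbar))
    pbar = np.nanmean(freqs, axis=1)
    return 2.0 * pbar * (1.0 - pbar)


@dataclass(frozen=True)
class HierFStats:
    """Hierarchical fixation indices: (1−f_st) = (1−f_sc)(1−f_ct)."""

    f_st: float
    f_sc: float
    f_ct: float


def hier_fstats(panel: GenotypePanel) -> HierFStats:
    """Multi-locus hierarchical F-statistics from a nested allele ANOVA.

    Gene copies are nested in populations nested in continental groups;
    per-locus variance components are summed over loci before taking
    ratios, so the (1−F) multiplicative identity holds exactly.
    F_CT measures differentiation among groups, F_SC among populations
    within groups.
    """
    pops = panel.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    groups = [panel.pop_group[p] for p in pops]
    ugroups = list(dict.fromkeys(groups))
    if len(ugroups) < 2:
        raise ValueError("single group: F_CT undefined")
    gidx = np.array([ugroups.index(g) for g in groups])
    freq, nd = panel.allele_frequencies()
    return hier_fstats_from_freqs(freq, 2.0 * nd, gidx)


def hier_fstats_from_freqs(freq: np.ndarray, n_copies: np.ndarray,
                           gidx: np.ndarray) -> HierFStats:
    """Hierarchical F-statistics from per-population frequency matrices.

    ``freq``: (loci × populations) allele frequencies (NaN where a
    population has no data); ``n_copies``: gene-copy counts; ``gidx``:
    group index of each population. Unequal sample sizes are handled with
    the standard nested-ANOVA coefficients.
    """
    freq = np.asarray(freq, dtype=float)
    n_copies = np.asarray(n_copies, dtype=float)
    gidx = np.asarray(gidx)
    n_loci = freq.shape[0]
    present = (n_copies > 0) & ~np.isnan(freq)
    n = np.where(present, n_copies, 0.0)
    p = np.where(present, np.nan_to_num(freq), 0.0)

    G = int(gidx.max()) + 1
    n_g = np.zeros((n_loci, G))
    sum_np_g = np.zeros((n_loci, G))
    sum_n2_g = np.zeros((n_loci, G))
    for k in range(G):
        cols = gidx == k
        n_g[:, k] = n[:, cols].sum(axis=1)
        sum_np_g[:, k] = (n * p)[:, cols].sum(axis=1)
        sum_n2_g[:, k] = (n[:, cols] ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_g = sum_np_g / n_g
    N = n_g.sum(axis=1)
    pbar = sum_np_g.sum(axis=1) / N

    # sums of squares for binary allele indicators
    ss_within = (n * p * (1 - p)).sum(axis=1)
    pg_per_pop = np.nan_to_num(p_g)[:, gidx]
    ss_pops = (n * (p - pg_per_pop) ** 2).sum(axis=1)
    ss_groups = (n_g * (np.nan_to_num(p_g) - pbar[:, None]) ** 2).sum(axis=1)

    P = present.sum(axis=1).astype(float)         # populations with data
    Gn = (n_g > 0).sum(axis=1).astype(float)      # groups with data
    df_w = N - P
    df_p = P - Gn
    df_g = Gn - 1
    ok = (df_w > 0) & (df_p > 0) & (df_g > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        ms_w = ss_within / df_w
        ms_p = ss_pops / df_p
        ms_g = ss_groups / df_g
        sum_n2_over_ng = np.where(n_g > 0, sum_n2_g / np.where(n_g > 0, n_g, 1), 0).sum(axis=1)
        n_prime = (N - sum_n2_over_ng) / df_p
        n_dprime = (sum_n2_over_ng - (n ** 2).sum(axis=1) / N) / df_g
        n_tprime = (N - (n_g ** 2).sum(axis=1) / N) / df_g

        sig_w = ms_w
        sig_p = (ms_p - ms_w) / n_prime
        sig_g = (ms_g - ms_w - n_dprime * sig_p) / n_tprime

    sw = np.nansum(np.where(ok, sig_w, np.nan))
    sp = np.nansum(np.where(ok, sig_p, np.nan))
    sg = np.nansum(np.where(ok, sig_g, np.nan))
    tot = sw + sp + sg
    return HierFStats(f_st=float((sg + sp) / tot), f_sc=float(sp / (sp + sw)),
                      f_ct=float(sg / tot))


def runs_test(values: np.ndarray, min_n: int = 20) -> float:
    """Wald–Wolfowitz runs test for spatial clustering along a chromosome.

    Values (ordered by position) are dichotomized at their median; ties at
    the median are dropped. One-sided toward *fewer* runs than expected,
    i.e. small p indicates clustering of like values. Normal approximation
    with continuity correction; requires n >= 20 after tie removal.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    keep = values != med
    x = values[keep] > med
    n1 = int(x.sum())
    n2 = int((~x).sum())
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate dichotomy: all values on one side of the median")
    if n < min_n:
        raise ValueError(f"runs_test requires n >= {min_n} for the normal approximation")
    runs = 1 + int((x[1:] != x[:-1]).sum())
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n ** 2 * (n - 1.0))
    z = (runs - mu + 0.5) / np.sqrt(var)   # continuity-corrected toward few runs
    return float(stats.norm.cdf(z))


def locus_stats_table(panel: GenotypePanel) -> pd.DataFrame:
    """Per-SNP scan table: fst and h_bp for every polymorphic SNP.

    Returns a DataFrame indexed like the panel with columns snp_id, chrom,
    pos, fst, h_bp; SNPs with undefined theta carry NaN and are dropped by
    downstream stages.
    """
    freq, _ = panel.allele_frequencies()
    return pd.DataFrame({
        "snp_id": panel.snp_ids,
        "chrom": panel.chrom,
        "pos": panel.pos,
        "fst": panel_fst(panel),
        "h_bp": h_bp(freq),
    })
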