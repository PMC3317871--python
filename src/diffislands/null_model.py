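"""Coalescent null distribution of (F_ST, H_BP) under island models.

The null genealogical process is a structured coalescent on a world of
demes: lineages within a deme coalesce pairwise at rate 1 (time in units
of 2N generations) and each lineage migrates at scaled rate M/2, where
M = 4Nm. Under the finite island model (FIM) the destination is uniform
over the other demes; under the hierarchical island model (HIM) a lineage
moves at total rate M1/2 to demes of its own group and M2/2 to demes of
other groups. One biallelic SNP per genealogy is created by dropping a
single mutation on a branch chosen proportionally to its length, which
guarantees polymorphism in the total sample; gene copies are paired
within demes into diploid genotypes, and F_ST / H_BP are computed on
exactly the sampled layout with the same estimators applied to observed
data.

The event loop is compiled with numba: the per-locus cost is dominated by
migration events, and stays at the microsecond scale even for the default
1,000-deme hierarchical world.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import stats

from .popgen_stats import (HierFStats, _theta_vectorized, hier_fstats_from_freqs,
                           theta_components_vectorized)

log = logging.getLogger("diffislands")


@dataclass(frozen=True)
class ModelConfig:
    """Island-model world, migration rates and sampled layout.

    ``m_within`` and ``m_between`` are scaled migration rates 4Nm (for the
    FIM only ``m_within`` is used). The sampled layout mirrors the
    observed data: ``sampled_groups`` groups, ``sampled_demes_per_group``
    demes in each, ``copies_per_deme`` gene copies (2 per diploid).
    """

    model: str = "HIM"                 # "HIM" | "FIM"
    n_groups: int = 10
    demes_per_group: int = 100
    m_within: float = 10.0
    m_between: float = 1.0
    sampled_groups: int = 4
    sampled_demes_per_group: int = 5
    copies_per_deme: int = 20
    n_loci: int = 50_000
    seed: int = 0
    #: minor-allele-frequency ascertainment threshold (total sample); set
    #: to the panel's ascertainment so the null mirrors the data's SNP
    #: character. 0 keeps every polymorphic genealogy.
    maf_min: float = 0.0

    def __post_init__(self):
        if self.model not in ("HIM", "FIM"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.m_within <= 0 or (self.model == "HIM" and self.m_between <= 0):
            raise ValueError("migration rates must be > 0")
        if self.model == "FIM" and self.n_groups != 1:
            raise ValueError("FIM has a single group of demes")
        if self.sampled_groups > self.n_groups:
            raise ValueError("cannot sample more groups than exist")
        if self.sampled_demes_per_group > self.demes_per_group:
            raise ValueError("cannot sample more demes per group than exist")
        if self.copies_per_deme % 2 or self.copies_per_deme < 2:
            raise ValueError("copies_per_deme must be an even number >= 2")


@dataclass
class NullTable:
    """Simulated joint null sample of (F_ST, H_BP)."""

    fst: np.ndarray
    h_bp: np.ndarray
    config: ModelConfig
    theta_a: np.ndarray | None = None      # WC numerator component per locus
    theta_abc: np.ndarray | None = None    # WC denominator component per locus

    def __len__(self) -> int:
        return len(self.fst)

    @property
    def multilocus_fst(self) -> float:
        """Ratio-of-sums theta over all simulated loci."""
        return float(np.nansum(self.theta_a) / np.nansum(self.theta_abc))


@njit(cache=True)
def _sim_derived(n_loci, deme_of_copy, n_demes, demes_per_group,
                 m_within, m_between, seed):          # pragma: no cover - numba
    """Simulate n_loci independent single-SNP genealogies.

    Returns a (n_loci, n_copies) uint8 matrix of derived-allele
    indicators for the sampled gene copies.
    """
    np.random.seed(seed)
    n = deme_of_copy.shape[0]
    n_groups = n_demes // demes_per_group
    out = np.zeros((n_loci, n), dtype=np.uint8)

    n_nodes = 2 * n - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    ntime = np.empty(n_nodes, dtype=np.float64)
    lin_node = np.empty(n, dtype=np.int64)
    lin_deme = np.empty(n, dtype=np.int64)
    cnt = np.zeros(n_demes, dtype=np.int64)

    m_tot = m_within + m_between

    for locus in range(n_loci):
        for v in range(n_nodes):
            parent[v] = -1
            ntime[v] = 0.0
        for d in range(n_demes):
            cnt[d] = 0
        for i in range(n):
            lin_node[i] = i
            lin_deme[i] = deme_of_copy[i]
            cnt[deme_of_copy[i]] += 1
        k = n
        coal_pairs = 0.0
        for d in range(n_demes):
            coal_pairs += cnt[d] * (cnt[d] - 1) / 2.0
        t = 0.0
        next_node = n

        while k > 1:
            mig_rate = k * m_tot / 2.0
            total = coal_pairs + mig_rate
            t += np.random.exponential(1.0 / total)
            if np.random.random() * total < coal_pairs:
                # coalescence: choose deme proportional to C(cnt, 2)
                u = np.random.random() * coal_pairs
                acc = 0.0
                deme = -1
                for d in range(n_demes):
                    if cnt[d] >= 2:
                        acc += cnt[d] * (cnt[d] - 1) / 2.0
                        if u < acc:
                            deme = d
                            break
                if deme < 0:           # numerical edge: take the last eligible
                    for d in range(n_demes - 1, -1, -1):
                        if cnt[d] >= 2:
                            deme = d
                            break
                # pick two distinct lineages in that deme
                a = np.random.randint(cnt[deme])
                b = np.random.randint(cnt[deme] - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                seen = 0
                for i in range(k):
                    if lin_deme[i] == deme:
                        if seen == a:
                            ia = i
                        if seen == b:
                            ib = i
                        seen += 1
                v = next_node
                next_node += 1
                ntime[v] = t
                parent[lin_node[ia]] = v
                parent[lin_node[ib]] = v
                coal_pairs -= cnt[deme] * (cnt[deme] - 1) / 2.0
                cnt[deme] -= 1
                coal_pairs += cnt[deme] * (cnt[deme] - 1) / 2.0
                lin_node[ia] = v
                # remove ib by swapping in the last lineage
                lin_node[ib] = lin_node[k - 1]
                lin_deme[ib] = lin_deme[k - 1]
                k -= 1
            else:
                i = np.random.randint(k)
                d = lin_deme[i]
                g = d // demes_per_group
                if n_groups == 1 or np.random.random() * m_tot < m_within:
                    # within-group move, uniform over the other demes of g
                    if demes_per_group > 1:
                        j = np.random.randint(demes_per_group - 1)
                        local = d - g * demes_per_group
                        if j >= local:
                            j += 1
                        target = g * demes_per_group + j
                    else:
                        target = d
                else:
                    j = np.random.randint((n_groups - 1) * demes_per_group)
                    if j >= g * demes_per_group:
                        j += demes_per_group
                    target = j
                if target != d:
                    coal_pairs -= cnt[d] * (cnt[d] - 1) / 2.0
                    coal_pairs -= cnt[target] * (cnt[target] - 1) / 2.0
                    cnt[d] -= 1
                    cnt[target] += 1
                    coal_pairs += cnt[d] * (cnt[d] - 1) / 2.0
                    coal_pairs += cnt[target] * (cnt[target] - 1) / 2.0
                    lin_deme[i] = target

        root = lin_node[0]
        # branch lengths; the root has none
        total_len = 0.0
        for v in range(next_node):
            if v != root and parent[v] >= 0:
                total_len += ntime[parent[v]] - ntime[v]
        x = np.random.random() * total_len
        acc = 0.0
        mut = -1
        for v in range(next_node):
            if v != root and parent[v] >= 0:
                acc += ntime[parent[v]] - ntime[v]
                if x < acc:
                    mut = v
                    break
        if mut < 0:
            mut = root - 1 if root > 0 else 1
        # a leaf is derived iff `mut` lies on its path to the root
        for leaf in range(n):
            v = leaf
            while v != -1:
                if v == mut:
                    out[locus, leaf] = 1
                    break
                v = parent[v]
    return out


def _sample_layout(config: ModelConfig) -> np.ndarray:
    """Deme index of every sampled gene copy (first demes of first groups)."""
    demes = []
    for g in range(config.sampled_groups):
        for d in range(config.sampled_demes_per_group):
            demes.append(g * config.demes_per_group + d)
    return np.repeat(np.asarray(demes, dtype=np.int64), config.copies_per_deme)


def _stats_from_derived(derived: np.ndarray, config: ModelConfig):
    """Per-locus (fst, h_bp) plus per-deme frequency/copy matrices."""
    n_loci = derived.shape[0]
    n_demes_s = config.sampled_groups * config.sampled_demes_per_group
    cpd = config.copies_per_deme
    copies = derived.reshape(n_loci, n_demes_s, cpd)
    geno = copies.reshape(n_loci, n_demes_s, cpd // 2, 2).sum(axis=3)  # diploids
    freq = copies.mean(axis=2)
    n_dip = np.full((n_loci, n_demes_s), cpd // 2)
    het = (geno == 1).mean(axis=2)
    fst = _theta_vectorized(freq, n_dip.astype(float), het)
    a, abc = theta_components_vectorized(freq, n_dip.astype(float), het)
    hbp = 2.0 * freq.mean(axis=1) * (1.0 - freq.mean(axis=1))
    return fst, hbp, freq, a, abc


def _derived_matrix(config: ModelConfig, n_loci: int, seed: int) -> np.ndarray:
    """Derived-allele indicators for n_loci genealogies, honouring the
    config's MAF ascertainment (rejected loci are replaced)."""
    m_between = config.m_between if config.model == "HIM" else 0.0
    deme_of_copy = _sample_layout(config)
    n_demes = config.n_groups * config.demes_per_group

    def batch(n, s):
        return _sim_derived(n, deme_of_copy, n_demes, config.demes_per_group,
                            config.m_within, m_between, s % (2 ** 31))

    if config.maf_min <= 0.0:
        return batch(n_loci, seed)
    kept = []
    n_have = 0
    for attempt in range(60):
        d = batch(int((n_loci - n_have) * 1.4) + 50, seed + 101 * attempt)
        maf = d.mean(axis=1)
        ok = np.minimum(maf, 1 - maf) >= config.maf_min
        kept.append(d[ok])
        n_have += int(ok.sum())
        if n_have >= n_loci:
            return np.concatenate(kept)[:n_loci]
    raise RuntimeError("MAF ascertainment keeps rejecting loci; lower maf_min")


def simulate_null(config: ModelConfig) -> NullTable:
    """Simulate the joint null table of (F_ST, H_BP) for a model config."""
    derived = _derived_matrix(config, config.n_loci, config.seed)
    fst, hbp, _, a, abc = _stats_from_derived(derived, config)
    keep = ~np.isnan(fst)
    return NullTable(fst=fst[keep], h_bp=hbp[keep], config=config,
                     theta_a=a[keep], theta_abc=abc[keep])


def simulate_locus(config: ModelConfig, seed: int) -> tuple[float, float]:
    """One draw from the joint null: convenience wrapper around the kernel."""
    table = simulate_null(replace(config, n_loci=1, seed=seed))
    if len(table) == 0:               # theta undefined (all copies identical by pairing)
        return simulate_locus(config, seed + 1)
    return float(table.fst[0]), float(table.h_bp[0])


def _simulated_hier(config: ModelConfig, n_loci: int, seed: int) -> HierFStats:
    derived = _derived_matrix(config, n_loci, seed)
    _, _, freq, _, _ = _stats_from_derived(derived, config)
    n_demes_s = config.sampled_groups * config.sampled_demes_per_group
    gidx = np.repeat(np.arange(config.sampled_groups), config.sampled_demes_per_group)
    n_copies = np.full((n_loci, n_demes_s), float(config.copies_per_deme))
    return hier_fstats_from_freqs(freq, n_copies, gidx)


class CalibrationError(RuntimeError):
    """Migration calibration failed to converge; carries the best config."""

    def __init__(self, msg, best_config, achieved):
        super().__init__(msg)
        self.best_config = best_config
        self.achieved = achieved


def calibrate_migration(target: HierFStats, config: ModelConfig,
                        tol: float = 0.005, pilot_loci: int = 2000,
                        n_rounds: int = 3, bisect_steps: int = 9,
                        bracket_factor: float = 64.0):
    """Find (M1, M2) whose simulated mean F_SC / F_CT match the target.

    Coordinate-wise bisection on log M1 (driving F_SC) and log M2 (driving
    F_CT), with pilot simulations of ``pilot_loci`` loci per evaluation.
    All pilots of a round share one random seed (common random numbers),
    which makes the pilot objective a smooth monotone function of the
    migration rate so that bisection converges to the pilot noise level;
    each round's closing check uses a fresh seed. Returns
    (calibrated config, achieved HierFStats).
    """
    if not (0 < target.f_sc < 1 and 0 < target.f_ct < 1):
        raise ValueError("target f_sc and f_ct must lie in (0, 1)")

    # island-model moment guesses M ~ (1 - F)/F as bracket centres
    m1 = (1 - target.f_sc) / target.f_sc
    m2 = ((1 - target.f_ct) / target.f_ct) / (2.0 * config.n_groups)
    base_seed = config.seed % (2 ** 31)

    def pilot(m1_, m2_, seed):
        c = replace(config, m_within=float(m1_), m_between=float(m2_))
        return _simulated_hier(c, pilot_loci, seed)

    def bisect(center, other_coord, attr, seed):
        lo, hi = np.log(center / bracket_factor), np.log(center * bracket_factor)
        mid = np.log(center)
        for step in range(bisect_steps):
            if attr == "f_sc":
                sim = pilot(np.exp(mid), other_coord, seed)
            else:
                sim = pilot(other_coord, np.exp(mid), seed)
            err = getattr(sim, attr) - getattr(target, attr)
            if abs(err) <= 0.5 * tol:
                return float(np.exp(mid))
            if err > 0:
                lo = mid        # too much structure -> raise migration
            else:
                hi = mid
            mid = 0.5 * (lo + hi)
        return float(np.exp(mid))

    best = None
    best_err = np.inf
    for rnd in range(n_rounds):
        crn_seed = (base_seed + 1000 * rnd + 1) % (2 ** 31)
        m1 = bisect(m1, m2, "f_sc", crn_seed)
        m2 = bisect(m2, m1, "f_ct", crn_seed)
        achieved = pilot(m1, m2, (base_seed + 1000 * rnd + 500) % (2 ** 31))
        err = max(abs(achieved.f_sc - target.f_sc), abs(achieved.f_ct - target.f_ct))
        if err < best_err:
            best_err = err
            best = (replace(config, m_within=m1, m_between=m2), achieved)
        log.info("calibration round %d: M1=%.3f M2=%.3f -> f_sc=%.4f f_ct=%.4f",
                 rnd + 1, m1, m2, achieved.f_sc, achieved.f_ct)
        if err <= tol:
            return best
    if best_err <= 2 * tol:
        return best
    raise CalibrationError(
        f"calibration did not converge: achieved {best[1]}, target {target}",
        best[0], best[1])


# ---------------------------------------------------------------------------
# Empirical p-values and the normal-score transform
# ---------------------------------------------------------------------------

def empirical_quantile(obs_fst: np.ndarray, obs_hbp: np.ndarray,
                       null: NullTable, n_het_bins: int = 20,
                       min_bin: int = 50) -> np.ndarray:
    """Lower-tail quantile of each observed F_ST within its H_BP bin.

    Null loci are split into equal-count heterozygosity bins; within the
    observed locus's bin q = (#{sim < obs} + ½·#{sim = obs} + 0.5) /
    (n_bin + 1), strictly inside (0, 1). If equal-count binning would
    leave fewer than ``min_bin`` loci per bin, the bin count is reduced
    (logged).
    """
    obs_fst = np.asarray(obs_fst, dtype=float)
    obs_hbp = np.asarray(obs_hbp, dtype=float)
    n_null = len(null)
    bins = n_het_bins
    if n_null // bins < min_bin:
        bins = max(1, n_null // min_bin)
        log.warning("het bins reduced from %d to %d (null too small)", n_het_bins, bins)
    edges = np.quantile(null.h_bp, np.linspace(0, 1, bins + 1)[1:-1]) if bins > 1 else np.array([])
    null_bin = np.searchsorted(edges, null.h_bp, side="right")
    obs_bin = np.searchsorted(edges, obs_hbp, side="right")
    q = np.empty(len(obs_fst))
    for b in range(bins):
        sim = np.sort(null.fst[null_bin == b])
        m = obs_bin == b
        if not m.any():
            continue
        lo = np.searchsorted(sim, obs_fst[m], side="left")
        hi = np.searchsorted(sim, obs_fst[m], side="right")
        q[m] = (lo + 0.5 * (hi - lo) + 0.5) / (len(sim) + 1.0)
    return q


def z_transform(q: np.ndarray) -> np.ndarray:
    """Normal score z = Φ⁻¹(q); q must lie strictly inside (0, 1)."""
    q = np.asarray(q, dtype=float)
    if ((q <= 0) | (q >= 1)).any():
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    return stats.norm.ppf(q)


def scan_panel(panel, null: NullTable, n_het_bins: int = 20):
    """Full selection scan: per-SNP F_ST, H_BP, quantile, p-values and z.

    Returns the locus-stats DataFrame restricted to SNPs with defined
    F_ST, with columns q, p_high (evidence for high differentiation),
    p_low and z appended.
    """
    from .popgen_stats import locus_stats_table
    tab = locus_stats_table(panel)
    tab = tab[~tab["fst"].isna()].reset_index(drop=True)
    q = empirical_quantile(tab["fst"].to_numpy(), tab["h_bp"].to_numpy(),
                           null, n_het_bins=n_het_bins)
    tab["q"] = q
    tab["p_high"] = 1.0 - q
    tab["p_low"] = q
    tab["z"] = z_transform(q)
    return tab
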