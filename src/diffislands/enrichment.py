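"""Downstream association and permutation analyses on islands.

Permutation machinery keeps the observed island/gap length structure:
per chromosome, the alternating sequence of island blocks and gap blocks
is uniformly re-ordered, which preserves both the number and the sizes
of islands while randomizing their positions. Conditioned permutations
additionally reject placements that touch any gene, for questions about
islands that carry no gene at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.weightstats import CompareMeans, DescrStatsW
import statsmodels.api as sm

from .io_core import AnnotationTrack, RecombinationMap
from .hmm_islands import Island

log = logging.getLogger("diffislands")


@dataclass
class EnrichmentResult:
    """Outcome of one association test."""

    test: str
    statistic: float
    p_value: float
    direction: str = ""            # "enriched" | "depleted" | ""
    null_mean: float = np.nan
    null_q05: float = np.nan
    null_q95: float = np.nan
    n_permutations: int = 0
    seed: int | None = None
    extra: dict | None = None


# ---------------------------------------------------------------------------
# interval helpers (half-open, 0-based throughout this module)
# ---------------------------------------------------------------------------

def _merge(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping sorted intervals."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts)
    s, e = starts[order], ends[order]
    ms, me = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.asarray(ms), np.asarray(me)


def _overlap_bp(s1, e1, s2, e2) -> np.ndarray:
    """Per-interval overlap of (s1,e1) with the merged set (s2,e2)."""
    s2, e2 = _merge(np.asarray(s2), np.asarray(e2))
    out = np.zeros(len(s1), dtype=np.int64)
    if len(s2) == 0:
        return out
    for i, (a, b) in enumerate(zip(s1, e1)):
        lo = np.searchsorted(e2, a, side="right")
        hi = np.searchsorted(s2, b, side="left")
        for j in range(lo, hi):
            out[i] += min(b, e2[j]) - max(a, s2[j])
    return out


def _points_in_intervals(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: 0-based point covered by any half-open interval."""
    starts, ends = _merge(np.asarray(starts), np.asarray(ends))
    if len(starts) == 0:
        return np.zeros(len(points), dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(points), dtype=bool)
    res[ok] = points[ok] < ends[idx[ok]]
    return res


def islands_to_intervals(islands: list[Island]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Island spans as 0-based half-open intervals keyed by chromosome."""
    out: dict[str, list] = {}
    for isl in islands:
        out.setdefault(isl.chrom, []).append((isl.start - 1, isl.end))
    return {c: (np.array([a for a, _ in v]), np.array([b for _, b in v]))
            for c, v in out.items()}


def island_gene_overlap(islands: list[Island], genes: AnnotationTrack) -> np.ndarray:
    """bp of gene overlap per island — the shared genic/non-genic predicate."""
    by_chrom = genes.by_chrom()
    out = np.zeros(len(islands), dtype=np.int64)
    for i, isl in enumerate(islands):
        if isl.chrom in by_chrom:
            s, e = by_chrom[isl.chrom]
            out[i] = _overlap_bp(np.array([isl.start - 1]), np.array([isl.end]), s, e)[0]
    return out


def genic_mask(islands: list[Island], genes: AnnotationTrack) -> np.ndarray:
    """True where the island overlaps at least one gene."""
    return island_gene_overlap(islands, genes) > 0


# ---------------------------------------------------------------------------
# block permutation
# ---------------------------------------------------------------------------

def _block_layout(starts, ends, chrom_len):
    """Decompose a chromosome into alternating gap/island block lengths.

    Returns (block_lengths, is_island) in positional order, beginning and
    ending with a (possibly zero-length) gap.
    """
    order = np.argsort(starts)
    s, e = starts[order], ends[order]
    if (e > chrom_len).any():
        raise ValueError("island extends past chromosome end")
    blocks, is_isl = [], []
    cur = 0
    for a, b in zip(s, e):
        blocks.append(a - cur)
        is_isl.append(False)
        blocks.append(b - a)
        is_isl.append(True)
        cur = b
    blocks.append(chrom_len - cur)
    is_isl.append(False)
    return np.asarray(blocks, dtype=np.int64), np.asarray(is_isl, dtype=bool)


def _permute_layout(blocks, is_isl, rng):
    """Uniformly re-order all blocks; island placements in the new layout."""
    order = rng.permutation(len(blocks))
    pos = np.cumsum(np.r_[0, blocks[order][:-1]])
    isl = is_isl[order]
    return pos[isl], pos[isl] + blocks[order][isl]


def permute_block_overlap(islands: list[Island], features: AnnotationTrack,
                          chrom_lengths: dict[str, int], n_perm: int = 10_000,
                          seed: int = 0, statistic: str = "count",
                          alternative: str = "two-sided") -> EnrichmentResult:
    """Island/feature overlap against the block-permutation null.

    ``statistic``: "count" (islands overlapping ≥1 feature) or "bp"
    (total overlap). Islands and gaps are permuted per chromosome;
    two-sided empirical p compares |null − null mean| with |obs − mean|.
    """
    rng = np.random.default_rng(seed)
    feat = features.by_chrom()
    layouts = {}
    for chrom, (s, e) in islands_to_intervals(islands).items():
        if chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length for {chrom!r}")
        layouts[chrom] = _block_layout(s, e, chrom_lengths[chrom])

    def measure(intervals_by_chrom):
        tot = 0.0
        for chrom, (s, e) in intervals_by_chrom.items():
            if chrom not in feat:
                continue
            ov = _overlap_bp(s, e, *feat[chrom])
            tot += (ov > 0).sum() if statistic == "count" else ov.sum()
        return tot

    obs = measure(islands_to_intervals(islands))
    null = np.empty(n_perm)
    for it in range(n_perm):
        perm = {c: _permute_layout(b, m, rng) for c, (b, m) in layouts.items()}
        null[it] = measure(perm)
    mean = null.mean()
    if alternative == "two-sided":
        extreme = np.abs(null - mean) >= np.abs(obs - mean) - 1e-12
    elif alternative == "greater":
        extreme = null >= obs - 1e-12
    else:
        extreme = null <= obs + 1e-12
    p = (extreme.sum() + 1.0) / (n_perm + 1.0)
    return EnrichmentResult(
        test=f"block_permutation_{statistic}", statistic=float(obs),
        p_value=float(p), direction="enriched" if obs > mean else "depleted",
        null_mean=float(mean), null_q05=float(np.quantile(null, 0.05)),
        null_q95=float(np.quantile(null, 0.95)), n_permutations=n_perm, seed=seed)


def conditioned_permute(islands: list[Island], genes: AnnotationTrack,
                        chrom_lengths: dict[str, int], n_perm: int = 1000,
                        seed: int = 0, statistic: str = "distance",
                        tfbs: AnnotationTrack | None = None,
                        max_tries: int = 1000,
                        alternative: str = "two-sided") -> EnrichmentResult:
    """Permutation test for non-genic islands, conditioned on avoiding genes.

    Each island is re-placed uniformly among the positions on its
    chromosome where it would overlap no gene (rejection sampling).
    ``statistic``: "distance" (mean distance to the closest gene, bp) or
    "tfbs" (count of islands overlapping ≥1 TFBS, requires ``tfbs``).
    """
    if statistic == "tfbs" and tfbs is None:
        raise ValueError("statistic='tfbs' requires a TFBS track")
    non_genic = [isl for isl in islands if not genic_mask([isl], genes)[0]]
    if not non_genic:
        raise ValueError("no non-genic islands to permute")
    rng = np.random.default_rng(seed)
    gene_by_chrom = {c: _merge(*se) for c, se in genes.by_chrom().items()}
    tf_by_chrom = tfbs.by_chrom() if tfbs is not None else {}

    def dist_to_gene(chrom, a, b):
        if chrom not in gene_by_chrom or len(gene_by_chrom[chrom][0]) == 0:
            return np.nan
        s, e = gene_by_chrom[chrom]
        left = e[e <= a]
        right = s[s >= b]
        d = []
        if len(left):
            d.append(a - left[-1])
        if len(right):
            d.append(right[0] - b)
        return float(min(d)) if d else np.nan

    def measure(placements):
        if statistic == "distance":
            vals = [dist_to_gene(c, a, b) for c, a, b in placements]
            return float(np.nanmean(vals))
        cnt = 0
        for c, a, b in placements:
            if c in tf_by_chrom and _overlap_bp(np.array([a]), np.array([b]), *tf_by_chrom[c])[0] > 0:
                cnt += 1
        return float(cnt)

    def feasible_starts(chrom, size):
        """Gene-free start segments [(lo, hi)] with hi inclusive."""
        L = chrom_lengths[chrom]
        gs, ge = gene_by_chrom.get(chrom, (np.empty(0, int), np.empty(0, int)))
        gaps, cur = [], 0
        for s, e in zip(gs, ge):
            gaps.append((cur, s))
            cur = e
        gaps.append((cur, L))
        return [(lo, hi - size) for lo, hi in gaps if hi - lo >= size]

    obs = measure([(isl.chrom, isl.start - 1, isl.end) for isl in non_genic])
    null = np.empty(n_perm)
    for it in range(n_perm):
        placements = []
        for isl in non_genic:
            L = chrom_lengths[isl.chrom]
            size = isl.end - (isl.start - 1)
            gs, ge = gene_by_chrom.get(isl.chrom, (np.empty(0, int), np.empty(0, int)))
            placed = False
            for attempt in range(max_tries):
                a = int(rng.integers(0, L - size + 1))
                b = a + size
                if len(gs) == 0 or _overlap_bp(np.array([a]), np.array([b]), gs, ge)[0] == 0:
                    placements.append((isl.chrom, a, b))
                    placed = True
                    break
            if not placed:
                # rejection keeps missing a narrow feasible region: draw
                # directly from the enumerated gene-free start segments
                segs = feasible_starts(isl.chrom, size)
                if not segs:
                    raise RuntimeError(
                        f"no gene-free placement exists for a {size}-bp "
                        f"island on {isl.chrom}")
                widths = np.array([hi - lo + 1 for lo, hi in segs], dtype=float)
                k = rng.choice(len(segs), p=widths / widths.sum())
                a = int(rng.integers(segs[k][0], segs[k][1] + 1))
                placements.append((isl.chrom, a, a + size))
        null[it] = measure(placements)
    mean = null.mean()
    if alternative == "two-sided":
        extreme = np.abs(null - mean) >= np.abs(obs - mean) - 1e-12
    elif alternative == "greater":
        extreme = null >= obs - 1e-12
    else:
        extreme = null <= obs + 1e-12
    p = (extreme.sum() + 1.0) / (n_perm + 1.0)
    return EnrichmentResult(
        test=f"conditioned_permutation_{statistic}", statistic=obs,
        p_value=float(p), direction="enriched" if obs > mean else "depleted",
        null_mean=float(mean), null_q05=float(np.quantile(null, 0.05)),
        null_q95=float(np.quantile(null, 0.95)), n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# categorical / rank / regression tests
# ---------------------------------------------------------------------------

def fisher_category_test(in_set, universe, flags, category: str = "genic") -> EnrichmentResult:
    """Fisher exact test: is a SNP category over-represented in a SNP set?

    2x2 table (in set vs rest of universe) x (category vs not); two-sided
    p with the odds ratio, direction as +/- enrichment.
    """
    in_set = set(in_set)
    universe = list(universe)
    if not in_set <= set(universe):
        raise ValueError("in_set must be a subset of the universe")
    flag_map = dict(zip(flags.snp_ids, getattr(flags, category)))
    flag = np.array([bool(flag_map[s]) for s in universe])
    member = np.array([s in in_set for s in universe])
    table = np.array([
        [int((member & flag).sum()), int((member & ~flag).sum())],
        [int((~member & flag).sum()), int((~member & ~flag).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return EnrichmentResult(test=f"fisher_{category}", statistic=np.nan,
                                p_value=1.0, direction="",
                                extra={"table": table.tolist(), "degenerate": True})
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        test=f"fisher_{category}", statistic=float(odds), p_value=float(p),
        direction="enriched" if odds > 1 else "depleted",
        extra={"table": table.tolist()})


def _mwu_exact_greater(x, y) -> float:
    """Exact one-sided (greater) Mann-Whitney p by enumeration of all
    label assignments; handles ties, so it works where scipy's exact
    method refuses."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:nx].sum()
    tot = 0
    ge = 0
    for comb in combinations(range(len(pooled)), nx):
        tot += 1
        if ranks[list(comb)].sum() >= obs - 1e-9:
            ge += 1
    return ge / tot


def mwu_fst_compare(fst_focus, fst_other, alternative: str = "greater") -> EnrichmentResult:
    """One-sided Mann-Whitney U comparing F_ST of two SNP classes.

    ``alternative='greater'`` tests whether the focus class (e.g.
    non-synonymous SNPs in high-differentiation islands) has larger
    F_ST. Exact enumeration when both samples have n ≤ 8, otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(fst_focus, dtype=float)
    y = np.asarray(fst_other, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(np.unique(np.concatenate([x, y]))) == 1:
        return EnrichmentResult(test="mannwhitney_fst", statistic=float(len(x) * len(y) / 2),
                                p_value=1.0, direction="")
    if len(x) <= 8 and len(y) <= 8:
        p = _mwu_exact_greater(x, y) if alternative == "greater" else _mwu_exact_greater(-x, -y)
        u = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic").statistic
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        u, p = res.statistic, res.pvalue
    return EnrichmentResult(
        test="mannwhitney_fst", statistic=float(u), p_value=float(p),
        direction="enriched" if alternative == "greater" else "depleted")


def weighted_ttest_recomb(rates1, weights1, rates2, weights2) -> EnrichmentResult:
    """Weighted two-sample t-test for a difference in mean recombination rate.

    Weights act as frequency weights (an island's weight is the number of
    recombination-map windows it overlaps, a precision proxy). With all
    weights 1 this reduces exactly to the ordinary pooled t-test.
    """
    w1 = np.asarray(weights1, dtype=float)
    w2 = np.asarray(weights2, dtype=float)
    if w1.sum() <= 0 or w2.sum() <= 0:
        raise ValueError("zero total weight")
    d1 = DescrStatsW(np.asarray(rates1, dtype=float), weights=w1)
    d2 = DescrStatsW(np.asarray(rates2, dtype=float), weights=w2)
    t, p, dof = CompareMeans(d1, d2).ttest_ind(usevar="pooled")
    return EnrichmentResult(
        test="weighted_ttest_recomb", statistic=float(t), p_value=float(p),
        direction="enriched" if d1.mean > d2.mean else "depleted",
        extra={"mean1": float(d1.mean), "mean2": float(d2.mean), "dof": float(dof)})


def ancova_size_recomb(length_bp, mean_rate, genic, log_length: bool = True) -> dict:
    """Island size vs recombination rate, controlling for genic status.

    Ordinary least squares of log10(length) on rate, genic status and
    their interaction. Reports each class's slope with its t-test and the
    interaction (slope-difference) test. Centromere-spanning islands must
    be excluded by the caller.
    """
    y = np.log10(np.asarray(length_bp, dtype=float)) if log_length \
        else np.asarray(length_bp, dtype=float)
    rate = np.asarray(mean_rate, dtype=float)
    g = np.asarray(genic, dtype=float)
    for cls in (0.0, 1.0):
        m = g == cls
        if m.sum() < 3:
            raise ValueError("need >= 3 islands per genic class")
        if np.allclose(rate[m].std(), 0):
            raise ValueError(f"rate constant within genic={bool(cls)} class; slope undefined")
    X = sm.add_constant(np.column_stack([rate, g, rate * g]))
    fit = sm.OLS(y, X).fit()
    slope_nongenic = float(fit.params[1])
    slope_genic = float(fit.params[1] + fit.params[3])
    t_genic = fit.t_test(np.array([0.0, 1.0, 0.0, 1.0]))
    return {
        "slope_nongenic": slope_nongenic,
        "p_slope_nongenic": float(fit.pvalues[1]),
        "slope_genic": slope_genic,
        "p_slope_genic": float(t_genic.pvalue),
        "slope_difference": float(fit.params[3]),
        "p_interaction": float(fit.pvalues[3]),
        "r_squared": float(fit.rsquared),
        "n": int(len(y)),
    }


def assign_continent(freqs: pd.DataFrame, pop_group: dict[str, str],
                     groups: tuple[str, ...] = ("Africa", "Eurasia", "East Asia", "America")):
    """Assign each SNP to the continental group with the largest frequency contrast.

    ``freqs``: SNP x population allele-frequency table (NaN = population
    not callable). For each group g, Δ_g = |unweighted mean frequency in
    g − unweighted mean outside g|; the SNP goes to argmax Δ_g, ties
    broken by the fixed group order (logged). Returns (assignments Series,
    histogram Series). SNPs with no callable population inside some group
    are excluded (logged).
    """
    pops = list(freqs.columns)
    in_group = {g: [p for p in pops if pop_group[p] == g] for g in groups}
    for g, members in in_group.items():
        if not members:
            raise ValueError(f"group {g!r} has no populations")
    deltas = pd.DataFrame(index=freqs.index, columns=list(groups), dtype=float)
    for g in groups:
        inside = freqs[in_group[g]].mean(axis=1)
        outside = freqs[[p for p in pops if p not in in_group[g]]].mean(axis=1)
        deltas[g] = (inside - outside).abs()
    callable_ = deltas.notna().all(axis=1)
    if (~callable_).any():
        log.info("%d SNP(s) excluded from continental assignment (uncallable group)",
                 int((~callable_).sum()))
    deltas = deltas[callable_]
    assign = deltas.idxmax(axis=1)     # idxmax keeps the first (fixed order) on ties
    ties = (deltas.eq(deltas.max(axis=1), axis=0).sum(axis=1) > 1)
    if ties.any():
        log.info("%d SNP(s) with tied group contrast; first group kept", int(ties.sum()))
    hist = assign.value_counts().reindex(list(groups), fill_value=0)
    return assign, hist


def hotspot_islands(recmap: RecombinationMap, threshold: float = 10.0) -> AnnotationTrack:
    """Recombination hotspots: windows with standardized rate strictly > threshold,
    adjacent qualifying windows merged."""
    hot = recmap.rate > threshold
    c, s, e = [], [], []
    for chrom in np.unique(recmap.chrom.astype(str)):
        m = (recmap.chrom == chrom) & hot
        if not m.any():
            continue
        starts, ends = recmap.start[m], recmap.end[m]
        ms, me = [starts[0]], [ends[0]]
        for a, b in zip(starts[1:], ends[1:]):
            if a == me[-1]:
                me[-1] = b
            else:
                ms.append(a)
                me.append(b)
        c += [chrom] * len(ms)
        s += list(ms)
        e += list(me)
    return AnnotationTrack(chrom=np.array(c, dtype=object),
                           start=np.array(s, dtype=np.int64),
                           end=np.array(e, dtype=np.int64), kind="hotspot")


def chrom_count_correlation(island_counts, snp_counts) -> EnrichmentResult:
    """Pearson correlation of per-chromosome island counts with SNP counts."""
    x = np.asarray(island_counts, dtype=float)
    y = np.asarray(snp_counts, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 chromosomes")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("zero variance in counts")
    r, p = stats.pearsonr(x, y)
    return EnrichmentResult(test="chrom_count_correlation", statistic=float(r),
                            p_value=float(p),
                            direction="enriched" if r > 0 else "depleted")
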