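"""Synthetic hierarchically structured SNP panels with planted islands.

The generator emulates a worldwide SNP panel typed in populations that are
nested in continental groups. Allele frequencies follow a hierarchical
Balding–Nichols construction: for each SNP an ancestral frequency p0 is
drawn uniformly on (0.05, 0.95) (mimicking array ascertainment against
rare variants); each group's frequency is Beta-distributed with mean p0
and variance F_between·p0(1−p0); each deme's frequency is Beta around its
group frequency with variance F_within·p_g(1−p_g); genotypes are
Binomial(2, p_deme). Contiguous "planted" segments multiply the Beta
variance parameters to create stretches of elevated (H) or decreased (L)
differentiation — the ground truth that island callers are scored
against. Loci are independent given the planted state track (no linkage
disequilibrium is modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import (MISSING, AnnotationTrack, GenotypePanel, RecombinationMap)


@dataclass(frozen=True)
class PlantedSegment:
    """Planted truth segment: SNP index span [start, end) with a state."""

    chrom: str
    start_snp: int
    end_snp: int
    state: str          # "L", "I" or "H"
    multiplier: float = 1.0


@dataclass
class SynthSpec:
    """Study conditions for the synthetic panel generator.

    Defaults give a desk-scale world: 4 continental groups of 5 demes with
    10 diploid individuals each, and 3 chromosomes of 5,000 SNPs spanning
    100 Mb. F parameters are on the Balding–Nichols scale (the Beta
    variance fraction), with within-group differentiation 0.05 and
    between-group differentiation 0.08 — of the order observed among
    human continental groups.
    """

    n_groups: int = 4
    demes_per_group: int = 5
    individuals_per_deme: int = 10
    chrom_n_snps: dict[str, int] = field(default_factory=lambda: {"1": 5000, "2": 5000, "3": 5000})
    chrom_length_bp: dict[str, int] = field(default_factory=lambda: {"1": 10**8, "2": 10**8, "3": 10**8})
    f_within: float = 0.05
    f_between: float = 0.08
    planted: list[PlantedSegment] = field(default_factory=list)
    missingness: float = 0.01
    frac_monomorphic: float = 0.0
    gene_density: float = 8.0          # genes per Mb
    gene_length_bp: int = 30_000
    tfbs_per_gene: float = 2.0
    tfbs_length_bp: int = 500
    recmap_window_bp: int = 500_000
    hotspot_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missingness", "frac_monomorphic", "f_within", "f_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        by_chrom: dict[str, list[PlantedSegment]] = {}
        for seg in self.planted:
            if seg.state not in ("L", "I", "H"):
                raise ValueError(f"unknown planted state {seg.state!r}")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start_snp)
            for a, b in zip(segs, segs[1:]):
                if a.end_snp > b.start_snp:
                    raise ValueError(f"overlapping planted segments on chromosome {chrom}")


def _sample_distinct(rng: np.random.Generator, n: int, upper: int) -> np.ndarray:
    """n distinct integers from [0, upper), sorted; rejection-based so the
    cost does not depend on ``upper``."""
    if n > upper:
        raise ValueError("cannot draw more distinct values than the range holds")
    got = np.unique(rng.integers(0, upper, size=int(n * 1.05) + 16))
    while len(got) < n:
        got = np.unique(np.concatenate([got, rng.integers(0, upper, size=n)]))
    if len(got) > n:
        got = np.sort(rng.permutation(got)[:n])
    return got


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Beta sample with the given mean and variance f·mean·(1−mean).

    The Balding–Nichols parameterisation: shape = mean·(1−f)/f. f → 0
    degenerates to the mean itself; f must stay below 1.
    """
    f = np.broadcast_to(np.asarray(f, dtype=float), mean.shape)
    if (f >= 1.0).any():
        raise ValueError("variance fraction must be < 1")
    out = np.array(mean, dtype=float, copy=True)
    pos = f > 0
    if pos.any():
        lam = (1.0 - f[pos]) / f[pos]
        a = np.clip(mean[pos], 1e-12, 1 - 1e-12) * lam
        b = np.clip(1 - mean[pos], 1e-12, 1 - 1e-12) * lam
        out[pos] = rng.beta(a, b)
    return out


def state_track(spec: SynthSpec, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP planted state characters and variance multipliers."""
    n = spec.chrom_n_snps[chrom]
    states = np.full(n, "I", dtype=object)
    mult = np.ones(n)
    for seg in spec.planted:
        if seg.chrom != chrom:
            continue
        if seg.end_snp > n:
            raise ValueError("planted segment extends past chromosome")
        states[seg.start_snp:seg.end_snp] = seg.state
        mult[seg.start_snp:seg.end_snp] = seg.multiplier
    return states, mult


def synth_panel(spec: SynthSpec) -> tuple[GenotypePanel, dict[str, np.ndarray]]:
    """Generate a panel plus the planted truth track.

    Returns (panel, truth) where truth maps chromosome -> per-SNP state
    character ("L"/"I"/"H") aligned with the panel's SNP order.
    """
    rng = np.random.default_rng(spec.seed)
    n_pops = spec.n_groups * spec.demes_per_group
    n_indiv = n_pops * spec.individuals_per_deme

    deme_of_indiv = np.repeat(np.arange(n_pops), spec.individuals_per_deme)
    sample_ids = np.array([f"ind{j:04d}" for j in range(n_indiv)], dtype=object)
    sample_pop = np.array([f"pop{d:03d}" for d in deme_of_indiv], dtype=object)
    pop_group = {f"pop{d:03d}": f"group{d // spec.demes_per_group}" for d in range(n_pops)}

    all_ids, all_chrom, all_pos, all_geno = [], [], [], []
    truth: dict[str, np.ndarray] = {}
    for chrom, n_snps in spec.chrom_n_snps.items():
        L = spec.chrom_length_bp[chrom]
        pos = _sample_distinct(rng, n_snps, L) + 1
        states, mult = state_track(spec, chrom)
        truth[chrom] = states

        p0 = rng.uniform(0.05, 0.95, size=n_snps)
        fb = np.minimum(spec.f_between * mult, 0.999)
        fw = np.minimum(spec.f_within * mult, 0.999)
        # group frequencies: (n_snps, n_groups)
        pg = _beta_draw(rng, np.repeat(p0[:, None], spec.n_groups, axis=1),
                        np.repeat(fb[:, None], spec.n_groups, axis=1))
        # deme frequencies: (n_snps, n_pops)
        pd_ = _beta_draw(rng, np.repeat(pg, spec.demes_per_group, axis=1),
                         np.repeat(fw[:, None], n_pops, axis=1))
        geno = rng.binomial(2, pd_[:, deme_of_indiv]).astype(np.int8)

        if spec.frac_monomorphic > 0:
            mono = rng.random(n_snps) < spec.frac_monomorphic
            geno[mono] = 0
        if spec.missingness > 0:
            miss = rng.random(geno.shape) < spec.missingness
            geno[miss] = MISSING

        all_ids.append(np.array([f"snp_{chrom}_{i:06d}" for i in range(n_snps)], dtype=object))
        all_chrom.append(np.full(n_snps, chrom, dtype=object))
        all_pos.append(pos)
        all_geno.append(geno)

    panel = GenotypePanel(
        snp_ids=np.concatenate(all_ids),
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        genotypes=np.vstack(all_geno),
        sample_ids=sample_ids,
        sample_pop=sample_pop,
        pop_group=pop_group,
    )
    return panel, truth


def truth_intervals(spec: SynthSpec, panel: GenotypePanel) -> list[tuple[str, int, int, str]]:
    """Planted segments as 1-based inclusive bp spans of their member SNPs."""
    out = []
    for seg in spec.planted:
        if seg.state == "I":
            continue
        m = panel.chrom == seg.chrom
        pos = panel.pos[m]
        span = pos[seg.start_snp:seg.end_snp]
        if len(span):
            out.append((seg.chrom, int(span[0]), int(span[-1]), "HDI" if seg.state == "H" else "LDI"))
    return out


def coalescent_panel(config, chrom_n_snps: dict[str, int],
                     chrom_length_bp: dict[str, int],
                     maf_min: float = 0.05, seed: int = 0) -> GenotypePanel:
    """Neutral panel drawn from the island-model coalescent itself.

    Simulates independent single-SNP genealogies under ``config`` (a
    :class:`~diffislands.null_model.ModelConfig`) and keeps loci whose
    total-sample minor-allele frequency is at least ``maf_min``,
    emulating the ascertainment of genotyping arrays against rare
    variants. Each sampled deme becomes one population; groups follow the
    sampled layout. Use this generator when the analysis itself assumes
    the island-model null (e.g. to check that a correctly specified null
    yields uniform p-values): the Balding–Nichols generator in
    :func:`synth_panel` is a different process and matches the coalescent
    null only in its first moments.
    """
    from dataclasses import replace

    from .null_model import _derived_matrix

    rng = np.random.default_rng(seed)
    n_target = sum(chrom_n_snps.values())
    n_demes_s = config.sampled_groups * config.sampled_demes_per_group
    cpd = config.copies_per_deme
    derived = _derived_matrix(replace(config, maf_min=maf_min), n_target,
                              int(rng.integers(2 ** 31)))
    geno = derived.reshape(n_target, n_demes_s, cpd // 2, 2).sum(axis=3).astype(np.int8)
    geno = geno.reshape(n_target, n_demes_s * (cpd // 2))

    deme_of_indiv = np.repeat(np.arange(n_demes_s), cpd // 2)
    sample_ids = np.array([f"ind{j:04d}" for j in range(geno.shape[1])], dtype=object)
    sample_pop = np.array([f"pop{d:03d}" for d in deme_of_indiv], dtype=object)
    pop_group = {f"pop{d:03d}": f"group{d // config.sampled_demes_per_group}"
                 for d in range(n_demes_s)}

    ids, chroms, poss = [], [], []
    offset = 0
    for chrom, n_snps in chrom_n_snps.items():
        pos = _sample_distinct(rng, n_snps, chrom_length_bp[chrom]) + 1
        ids.append(np.array([f"snp_{chrom}_{i:06d}" for i in range(n_snps)], dtype=object))
        chroms.append(np.full(n_snps, chrom, dtype=object))
        poss.append(pos)
        offset += n_snps
    return GenotypePanel(
        snp_ids=np.concatenate(ids),
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        genotypes=geno,
        sample_ids=sample_ids,
        sample_pop=sample_pop,
        pop_group=pop_group,
    )


def synth_annotations(spec: SynthSpec) -> tuple[AnnotationTrack, AnnotationTrack, AnnotationTrack, RecombinationMap]:
    """Random annotation tracks matched to the synthetic genome.

    Genes are non-overlapping uniform placements at the requested density;
    TFBS cluster near gene starts; the recombination map tiles each
    chromosome with fixed windows whose standardized rates are log-normal,
    with a fraction of windows promoted to hotspots (rate > 10).
    """
    rng = np.random.default_rng(spec.seed + 1)
    gc, gs, ge = [], [], []
    tc, ts_, te = [], [], []
    rc, rs, re_, rr = [], [], [], []
    for chrom, L in spec.chrom_length_bp.items():
        n_genes = rng.poisson(spec.gene_density * L / 1e6)
        glen = spec.gene_length_bp
        if n_genes > 0 and n_genes * glen < L:
            # non-overlapping placement via the gap-allocation construction
            slack = L - n_genes * glen
            cuts = _sample_distinct(rng, n_genes, slack)
            starts = cuts + glen * np.arange(n_genes)
            for s in starts:
                gc.append(chrom); gs.append(int(s)); ge.append(int(s) + glen)
                n_tf = rng.poisson(spec.tfbs_per_gene)
                for _ in range(n_tf):
                    off = int(rng.integers(-20_000, 20_000))
                    t0 = max(0, int(s) + off)
                    t1 = min(L, t0 + spec.tfbs_length_bp)
                    if t1 > t0:
                        tc.append(chrom); ts_.append(t0); te.append(t1)
        w = spec.recmap_window_bp
        edges = np.arange(0, L + w, w)
        edges[-1] = min(edges[-1], L)
        for a, b in zip(edges[:-1], edges[1:]):
            if b <= a:
                continue
            if rng.random() < spec.hotspot_fraction:
                rate = 10.0 + rng.lognormal(1.0, 0.5)
            else:
                rate = min(10.0, rng.lognormal(-0.3, 0.8))
            rc.append(chrom); rs.append(int(a)); re_.append(int(b)); rr.append(rate)

    def _track(c, s, e, kind):
        return AnnotationTrack(chrom=np.array(c, dtype=object), start=np.array(s, dtype=np.int64),
                               end=np.array(e, dtype=np.int64), kind=kind)

    genes = _track(gc, gs, ge, "gene")
    tfbs = _track(tc, ts_, te, "tfbs")
    recmap = RecombinationMap(chrom=np.array(rc, dtype=object), start=np.array(rs, dtype=np.int64),
                              end=np.array(re_, dtype=np.int64), rate=np.array(rr))
    hot = np.asarray(recmap.rate) > 10.0
    hotspots = _track(list(recmap.chrom[hot]), list(recmap.start[hot]), list(recmap.end[hot]), "hotspot")
    return genes, tfbs, hotspots, recmap


def synth_category_flags(panel: GenotypePanel, genes: AnnotationTrack,
                         nonsyn_fraction: float = 0.05, seed: int = 0):
    """Assign genic/non-synonymous flags: a SNP is genic iff inside a gene;
    a random fraction of genic SNPs is marked non-synonymous."""
    from .enrichment import _points_in_intervals
    from .io_core import SnpCategoryFlags
    rng = np.random.default_rng(seed)
    genic = np.zeros(panel.n_snps, dtype=bool)
    for c, (s, e) in genes.by_chrom().items():
        m = panel.chrom == c
        genic[m] = _points_in_intervals(panel.pos[m] - 1, s, e)
    nonsyn = genic & (rng.random(panel.n_snps) < nonsyn_fraction)
    return SnpCategoryFlags(snp_ids=panel.snp_ids, genic=genic, non_synonymous=nonsyn)


def synth_filter_fixture(n_total: int = 660_918, n_all_missing: int = 12,
                         n_untyped_pop: int = 4, n_monomorphic: int = 50,
                         n_excluded: int = 188, seed: int = 0) -> GenotypePanel:
    """A lightweight worldwide-panel stand-in for exercising QC filtering.

    Builds the stated number of SNP records over a handful of individuals,
    with disjoint planted categories: all-missing records, records untyped
    in one whole population, monomorphic records, and records on excluded
    chromosomes (Y / X-Y pseudoautosomal / mtDNA). Everything else is
    clean and polymorphic.
    """
    rng = np.random.default_rng(seed)
    n_indiv = 6                       # two populations of three
    sample_ids = np.array([f"i{j}" for j in range(n_indiv)], dtype=object)
    sample_pop = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
    pop_group = {"A": "G1", "B": "G2"}

    geno = np.empty((n_total, n_indiv), dtype=np.int8)
    # clean default: deterministic polymorphic pattern with both alleles in both pops
    geno[:] = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)

    idx = np.arange(n_total)
    rng.shuffle(idx)
    k = 0
    i_missing = idx[k:k + n_all_missing]; k += n_all_missing
    i_untyped = idx[k:k + n_untyped_pop]; k += n_untyped_pop
    i_mono = idx[k:k + n_monomorphic]; k += n_monomorphic
    i_excl = idx[k:k + n_excluded]; k += n_excluded

    geno[i_missing] = MISSING
    geno[i_untyped, :3] = MISSING     # population A entirely untyped, B polymorphic
    geno[i_mono] = 0                  # all-reference: monomorphic in every population
    chrom = np.full(n_total, "1", dtype=object)
    chrom[i_excl] = np.array(["Y", "XY", "MT"], dtype=object)[
        np.arange(n_excluded) % 3]

    return GenotypePanel(
        snp_ids=np.array([f"rs{j}" for j in range(n_total)], dtype=object),
        chrom=chrom,
        pos=np.arange(1, n_total + 1, dtype=np.int64),
        genotypes=geno,
        sample_ids=sample_ids,
        sample_pop=sample_pop,
        pop_group=pop_group,
    )
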