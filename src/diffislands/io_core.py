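"""Panel construction, QC filtering and file formats.

Coordinate conventions are centralized here: SNP positions are 1-based
(VCF-like), annotation intervals are BED-style 0-based half-open. All
readers validate on construction; all writers round-trip losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("diffislands")

MISSING = -1  # in-memory code for a missing genotype ("NA" on disk)

#: chromosome labels removed by default in :func:`filter_panel` —
#: Y, the X/Y pseudoautosomal region and mitochondrial DNA.
DEFAULT_EXCLUDED_CHROMS = frozenset({"Y", "chrY", "XY", "chrXY", "M", "MT", "chrM", "chrMT"})

_X_LABELS = frozenset({"X", "chrX", "23"})


class PanelFormatError(ValueError):
    """Raised when a genotype/sample file violates the expected dialect."""


@dataclass
class GenotypePanel:
    """SNP x individual minor-allele dosage matrix with two-level sample structure.

    genotypes[i, j] is the dosage (0/1/2) of SNP i in individual j, or
    ``MISSING``. Individuals belong to populations, populations to
    continental groups. SNPs are sorted by (chrom, pos) with positions
    strictly increasing within each chromosome.
    """

    snp_ids: np.ndarray          # (n_snps,) str
    chrom: np.ndarray            # (n_snps,) str
    pos: np.ndarray              # (n_snps,) int64, 1-based
    genotypes: np.ndarray        # (n_snps, n_indiv) int8, MISSING = -1
    sample_ids: np.ndarray       # (n_indiv,) str
    sample_pop: np.ndarray       # (n_indiv,) str, population of each individual
    pop_group: dict[str, str]    # population -> continental group
    chrom_ploidy: dict[str, str] = field(default_factory=dict)  # chrom -> autosome|X

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.sample_pop = np.asarray(self.sample_pop, dtype=object)
        self._validate()
        self._sort()
        for c in self.chroms():
            self.chrom_ploidy.setdefault(c, "X" if c in _X_LABELS else "autosome")

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        n, m = self.genotypes.shape
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == n):
            raise PanelFormatError("per-SNP arrays disagree in length")
        if len(self.sample_ids) != m or len(self.sample_pop) != m:
            raise PanelFormatError("per-individual arrays disagree in length")
        ids, counts = np.unique(self.snp_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            raise PanelFormatError(f"duplicate SNP id(s): {ids[counts > 1][:5].tolist()}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelFormatError(
                f"invalid genotype value {self.genotypes[i, j]} at SNP "
                f"{self.snp_ids[i]!r}, individual {self.sample_ids[j]!r}"
            )
        missing_pop = set(self.sample_pop) - set(self.pop_group)
        if missing_pop:
            raise PanelFormatError(f"population(s) without a group: {sorted(missing_pop)}")

    def _sort(self) -> None:
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        self.snp_ids = self.snp_ids[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.genotypes = self.genotypes[order]
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and (np.diff(p) <= 0).any():
                raise PanelFormatError(f"duplicate position on chromosome {c}")

    # -- basic views ----------------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_pop:
            seen.setdefault(p)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(self.pop_group[p])
        return list(seen)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Column indices of each population's individuals."""
        return {p: np.flatnonzero(self.sample_pop == p) for p in self.populations}

    def take(self, mask: np.ndarray) -> "GenotypePanel":
        """Sub-panel of the SNPs selected by a boolean mask or index array."""
        return GenotypePanel(
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            genotypes=self.genotypes[mask],
            sample_ids=self.sample_ids,
            sample_pop=self.sample_pop,
            pop_group=dict(self.pop_group),
            chrom_ploidy=dict(self.chrom_ploidy),
        )

    def allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-population minor-allele frequencies and diploid sample sizes.

        Returns (freq, n) of shape (n_snps, n_pops), ``freq`` NaN where a
        population has no called genotype. Population order follows
        :attr:`populations`.
        """
        pops = self.populations
        n_snps = self.n_snps
        freq = np.full((n_snps, len(pops)), np.nan)
        size = np.zeros((n_snps, len(pops)), dtype=np.int64)
        g = self.genotypes
        for k, p in enumerate(pops):
            cols = np.flatnonzero(self.sample_pop == p)
            sub = g[:, cols]
            called = sub != MISSING
            n = called.sum(axis=1)
            dose = np.where(called, sub, 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq[:, k] = np.where(n > 0, dose / (2.0 * n), np.nan)
            size[:, k] = n
        return freq, size


@dataclass(frozen=True)
class FilterReport:
    """Count of SNPs removed at each sequential QC step."""

    n_all_missing: int
    n_untyped_population: int
    n_monomorphic: int
    n_excluded_chrom: int
    n_input: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return (self.n_all_missing + self.n_untyped_population
                + self.n_monomorphic + self.n_excluded_chrom)


def filter_panel(
    panel: GenotypePanel,
    excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
) -> tuple[GenotypePanel, FilterReport]:
    """QC-filter a panel, attributing each removed SNP to exactly one rule.

    Rules are applied sequentially so the per-rule counts are additive:
    (1) SNPs with only missing data; (2) SNPs not typed at all in at least
    one population; (3) SNPs monomorphic across all populations; (4) SNPs
    on excluded chromosomes (Y, X/Y pseudoautosomal, mtDNA).
    """
    g = panel.genotypes
    called = g != MISSING
    alive = np.ones(panel.n_snps, dtype=bool)

    rule1 = ~called.any(axis=1)
    alive &= ~rule1

    rule2 = np.zeros(panel.n_snps, dtype=bool)
    for cols in panel.pop_indices().values():
        rule2 |= ~called[:, cols].any(axis=1)
    rule2 &= alive
    alive &= ~rule2

    dose = np.where(called, g, 0)
    tot = dose.sum(axis=1)
    ncall = called.sum(axis=1)
    rule3 = (tot == 0) | (tot == 2 * ncall)   # all-ref or all-alt among called
    rule3 &= alive
    alive &= ~rule3

    rule4 = np.isin(panel.chrom.astype(str), sorted(excluded_chroms))
    rule4 &= alive
    alive &= ~rule4

    report = FilterReport(
        n_all_missing=int(rule1.sum()),
        n_untyped_population=int(rule2.sum()),
        n_monomorphic=int(rule3.sum()),
        n_excluded_chrom=int(rule4.sum()),
        n_input=panel.n_snps,
        n_retained=int(alive.sum()),
    )
    return panel.take(alive), report


# ---------------------------------------------------------------------------
# Annotation tracks and recombination map
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTrack:
    """Genomic intervals (BED convention: 0-based, half-open)."""

    chrom: np.ndarray   # (n,) str
    start: np.ndarray   # (n,) int64
    end: np.ndarray     # (n,) int64
    kind: str = "gene"  # gene | tfbs | hotspot
    name: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.name is not None:
            self.name = np.asarray(self.name, dtype=object)
        if (self.start >= self.end).any():
            i = int(np.argmax(self.start >= self.end))
            raise ValueError(f"interval with start >= end: {self.chrom[i]}:{self.start[i]}-{self.end[i]}")
        order = np.lexsort((self.start, self.chrom.astype(str)))
        self.chrom = self.chrom[order]
        self.start = self.start[order]
        self.end = self.end[order]
        if self.name is not None:
            self.name = self.name[order]

    def __len__(self) -> int:
        return len(self.start)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted (start, end) arrays per chromosome."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in np.unique(self.chrom.astype(str)):
            m = self.chrom == c
            out[c] = (self.start[m], self.end[m])
        return out


@dataclass
class RecombinationMap:
    """Non-overlapping windows with standardized sex-averaged rates."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.rate = np.asarray(self.rate, dtype=float)
        if (self.start >= self.end).any():
            raise ValueError("recombination window with start >= end")
        if (self.rate < 0).any():
            raise ValueError("negative recombination rate")
        order = np.lexsort((self.start, self.chrom.astype(str)))
        for a in ("chrom", "start", "end", "rate"):
            setattr(self, a, getattr(self, a)[order])
        for c in np.unique(self.chrom.astype(str)):
            m = self.chrom == c
            if (self.end[m][:-1] > self.start[m][1:]).any():
                raise ValueError(f"overlapping recombination windows on {c}")

    def __len__(self) -> int:
        return len(self.rate)


@dataclass
class SnpCategoryFlags:
    """Per-SNP functional annotation: genic and non-synonymous booleans."""

    snp_ids: np.ndarray
    genic: np.ndarray
    non_synonymous: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.genic = np.asarray(self.genic, dtype=bool)
        self.non_synonymous = np.asarray(self.non_synonymous, dtype=bool)
        if (self.non_synonymous & ~self.genic).any():
            raise ValueError("non-synonymous SNP flagged non-genic")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_panel(genotype_path, samples_path) -> GenotypePanel:
    """Read a panel from a genotype TSV and a samples TSV.

    Genotype file: one row per SNP — columns ``snp_id``, ``chrom``, ``pos``
    then one dosage column per individual (0/1/2 or NA). Samples file:
    columns ``individual``, ``population``, ``group``.
    """
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    for col in ("individual", "population", "group"):
        if col not in samples.columns:
            raise PanelFormatError(f"samples file lacks column {col!r}")
    pop_group: dict[str, str] = {}
    for p, g in zip(samples["population"], samples["group"]):
        if pop_group.setdefault(p, g) != g:
            raise PanelFormatError(f"population {p!r} assigned to two groups")

    geno = pd.read_csv(genotype_path, sep="\t", dtype=str)
    fixed = ["snp_id", "chrom", "pos"]
    for col in fixed:
        if col not in geno.columns:
            raise PanelFormatError(f"genotype file lacks column {col!r}")
    try:
        pos = geno["pos"].astype(np.int64)
    except ValueError as exc:
        raise PanelFormatError("non-integer position in genotype file") from exc
    indiv_cols = [c for c in geno.columns if c not in fixed]
    unknown = set(indiv_cols) - set(samples["individual"])
    if unknown:
        raise PanelFormatError(f"genotype columns with no sample entry: {sorted(unknown)}")
    # order individuals as in the samples file
    indiv_cols = [i for i in samples["individual"] if i in indiv_cols]

    mat = np.full((len(geno), len(indiv_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(indiv_cols):
        vals = geno[col].fillna("NA").astype(str)
        ok = vals.isin(["NA", "0", "1", "2"])
        if not ok.all():
            row = int(np.argmax(~ok.to_numpy()))
            raise PanelFormatError(
                f"invalid genotype {vals.iloc[row]!r} for SNP "
                f"{geno['snp_id'].iloc[row]!r}, individual {col!r}"
            )
        v = vals.to_numpy(dtype=object)
        mat[:, j] = np.where(v == "NA", MISSING, np.where(v == "NA", "0", v).astype(np.int8))

    sample_pop = np.array(
        [samples.set_index("individual")["population"][i] for i in indiv_cols], dtype=object
    )
    return GenotypePanel(
        snp_ids=geno["snp_id"].to_numpy(dtype=object),
        chrom=geno["chrom"].to_numpy(dtype=object),
        pos=pos.to_numpy(),
        genotypes=mat,
        sample_ids=np.array(indiv_cols, dtype=object),
        sample_pop=sample_pop,
        pop_group=pop_group,
    )


def write_panel(panel: GenotypePanel, genotype_path, samples_path) -> None:
    """Write a panel in the TSV dialect accepted by :func:`read_panel`."""
    g = panel.genotypes.astype(object)
    g[panel.genotypes == MISSING] = "NA"
    cols = {"snp_id": panel.snp_ids, "chrom": panel.chrom, "pos": panel.pos}
    cols.update({ind: g[:, j] for j, ind in enumerate(panel.sample_ids)})
    pd.DataFrame(cols).to_csv(genotype_path, sep="\t", index=False)
    pd.DataFrame({
        "individual": panel.sample_ids,
        "population": panel.sample_pop,
        "group": [panel.pop_group[p] for p in panel.sample_pop],
    }).to_csv(samples_path, sep="\t", index=False)


def read_bed(path, kind: str = "gene") -> AnnotationTrack:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line with fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    if not rows:
        return AnnotationTrack(
            chrom=np.empty(0, dtype=object), start=np.empty(0, dtype=np.int64),
            end=np.empty(0, dtype=np.int64), kind=kind,
            name=np.empty(0, dtype=object),
        )
    c, s, e, n = zip(*rows)
    return AnnotationTrack(chrom=np.array(c, dtype=object), start=np.array(s),
                           end=np.array(e), kind=kind, name=np.array(n, dtype=object))


def write_bed(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(track)):
            name = track.name[i] if track.name is not None else ""
            cols = [str(track.chrom[i]), str(track.start[i]), str(track.end[i])]
            if name:
                cols.append(str(name))
            fh.write("\t".join(cols) + "\n")


def read_recmap(path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end", "rate"):
        if col not in df.columns:
            raise ValueError(f"recombination map lacks column {col!r}")
    return RecombinationMap(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        rate=df["rate"].to_numpy(dtype=float),
    )


def write_recmap(recmap: RecombinationMap, path) -> None:
    pd.DataFrame({"chrom": recmap.chrom, "start": recmap.start,
                  "end": recmap.end, "rate": recmap.rate}).to_csv(path, sep="\t", index=False)


def read_flags(path) -> SnpCategoryFlags:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    return SnpCategoryFlags(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        genic=df["genic"].astype(int).to_numpy(dtype=bool),
        non_synonymous=df["non_synonymous"].astype(int).to_numpy(dtype=bool),
    )


def write_flags(flags: SnpCategoryFlags, path) -> None:
    pd.DataFrame({"snp_id": flags.snp_ids, "genic": flags.genic.astype(int),
                  "non_synonymous": flags.non_synonymous.astype(int)}).to_csv(
        path, sep="\t", index=False)


_ISLAND_COLUMNS = ["chrom", "start", "end", "type", "n_snps", "n_fdr_snps",
                   "mean_fst", "mean_het", "mean_z", "length_bp"]


def write_islands(islands, tsv_path, bed_path=None) -> None:
    """Write called islands as a TSV (summary columns) and optionally BED.

    The BED uses 0-based half-open coordinates converted from the islands'
    1-based inclusive SNP spans.
    """
    rows = [{
        "chrom": isl.chrom, "start": isl.start, "end": isl.end, "type": isl.type,
        "n_snps": isl.n_snps, "n_fdr_snps": isl.n_fdr_snps,
        "mean_fst": isl.mean_fst, "mean_het": isl.mean_het, "mean_z": isl.mean_z,
        "length_bp": isl.length_bp,
        "snp_ids": ",".join(map(str, isl.snp_ids)),
    } for isl in islands]
    pd.DataFrame(rows, columns=_ISLAND_COLUMNS + ["snp_ids"]).to_csv(
        tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for isl in islands:
                fh.write(f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\t{isl.type}\n")


def read_islands(tsv_path):
    from .hmm_islands import Island  # deferred: avoid a module cycle
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    out = []
    for _, r in df.iterrows():
        snps = [] if pd.isna(r.get("snp_ids")) or r.get("snp_ids") == "" else str(r["snp_ids"]).split(",")
        out.append(Island(
            chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]), type=r["type"],
            n_snps=int(r["n_snps"]), n_fdr_snps=int(r["n_fdr_snps"]),
            mean_fst=float(r["mean_fst"]), mean_het=float(r["mean_het"]),
            mean_z=float(r["mean_z"]), snp_ids=snps,
        ))
    return out
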