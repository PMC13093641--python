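"""Genotype container, VCF I/O and the SNP filtering stages.

The filtering pipeline mirrors a standard ddRAD workflow: drop sites typed in
too few individuals, drop low minor-allele-count sites, then prune linked
SNPs by windowed r-squared. Dosages count ALT alleles (0/1/2) with ``-1``
marking a missing diploid genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "filter_call_rate",
    "filter_mac",
    "ld_prune",
    "apply_default_filters",
]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be interpreted as diploid biallelic SNPs."""


@dataclass
class GenotypeMatrix:
    """Diploid ALT-dosage matrix (individuals x biallelic sites).

    ``dosages`` is an int8 array with entries in {0, 1, 2, -1}; ``-1`` is a
    missing call. Sites are kept sorted by (chrom, pos) with 1-based VCF
    coordinates. ``pop_labels`` holds one label per individual (e.g. north /
    admix / south).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    pop_labels: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        d = self.dosages
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        ok = (d == MISSING) | ((d >= 0) & (d <= 2))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")
        n_ind, n_sites = d.shape
        if len(self.sample_ids) != n_ind or len(self.pop_labels) != n_ind:
            raise ValueError("sample_ids/pop_labels length mismatch")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length != number of sites")
        if n_sites:
            key = list(zip(self.chrom.tolist(), self.pos.tolist()))
            if len(set(key)) != n_sites:
                raise ValueError("duplicate (chrom, pos)")
            if key != sorted(key):
                raise ValueError("sites not sorted by (chrom, pos)")

    def sorted_copy(self) -> "GenotypeMatrix":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_sites(order)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.sample_ids), list(self.pop_labels),
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx])

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx], [self.sample_ids[i] for i in idx],
            [self.pop_labels[i] for i in idx],
            self.chrom, self.pos, self.ref, self.alt)

    def individuals_in(self, pops) -> np.ndarray:
        pops = {pops} if isinstance(pops, str) else set(pops)
        return np.array([i for i, p in enumerate(self.pop_labels) if p in pops],
                        dtype=np.int64)

    # -- per-site summaries --------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=0)

    def alt_count(self) -> np.ndarray:
        d = self.dosages.astype(np.int64)
        return np.where(d == MISSING, 0, d).sum(axis=0)

    def called_chromosomes(self) -> np.ndarray:
        return 2 * self.called_mask().sum(axis=0)

    def mac(self) -> np.ndarray:
        """Minor allele count among called genotypes (ALT vs REF copies)."""
        ac = self.alt_count()
        an = self.called_chromosomes()
        return np.minimum(ac, an - ac)

    def maf(self) -> np.ndarray:
        an = self.called_chromosomes()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(an > 0, self.mac() / np.maximum(an, 1), 0.0)
        return f

    def __eq__(self, other) -> bool:  # identity on content, for round-trips
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (np.array_equal(self.dosages, other.dosages)
                and self.sample_ids == other.sample_ids
                and self.pop_labels == other.pop_labels
                and all(np.array_equal(a, b) for a, b in (
                    (self.chrom, other.chrom), (self.pos, other.pos),
                    (self.ref, other.ref), (self.alt, other.alt))))


@dataclass
class FilterReport:
    n_input_sites: int = 0
    n_removed_call_rate: int = 0
    n_removed_mac: int = 0
    n_removed_ld: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        removed = (self.n_removed_call_rate + self.n_removed_mac
                   + self.n_removed_ld)
        if min(asdict(self).values()) < 0:
            raise ValueError("negative count in FilterReport")
        if self.n_input_sites != self.n_retained + removed:
            raise ValueError("FilterReport counts do not sum")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid, biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Uses cyvcf2; ``./.`` becomes missing. Multiallelic or non-diploid records
    raise :class:`VcfParseError`. Population labels default to "other" and can
    be attached afterwards from a metadata table.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    cols, chroms, poss, refs, alts = [], [], [], [], []
    for i, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise VcfParseError(
                f"record {i} ({var.CHROM}:{var.POS}): not biallelic")
        if var.ploidy != 2:
            raise VcfParseError(
                f"record {i} ({var.CHROM}:{var.POS}): not diploid")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], MISSING)
        cols.append(dos.astype(np.int8))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    n_sites = len(cols)
    dosages = (np.stack(cols, axis=1) if n_sites
               else np.zeros((len(samples), 0), dtype=np.int8))
    g = GenotypeMatrix(dosages, samples, ["other"] * len(samples),
                       np.array(chroms, dtype=object), np.array(poss),
                       np.array(refs, dtype=object), np.array(alts, dtype=object))
    return g.sorted_copy()


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only) re-readable by :func:`read_vcf`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=demogscape\n")
        seen = []
        for c in g.chrom:
            if c not in seen:
                seen.append(c)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for s in range(g.n_sites):
            gts = "\t".join(_GT[int(d)] for d in g.dosages[:, s])
            fh.write(f"{g.chrom[s]}\t{g.pos[s]}\t.\t{g.ref[s]}\t{g.alt[s]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filters


def filter_call_rate(g: GenotypeMatrix, min_rate: float = 0.8):
    """Drop sites typed in fewer than ``min_rate`` of individuals (inclusive
    boundary: a site at exactly ``min_rate`` is retained)."""
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    keep = g.call_rate() >= min_rate
    report = FilterReport(n_input_sites=g.n_sites,
                          n_removed_call_rate=int((~keep).sum()),
                          n_retained=int(keep.sum()))
    return g.take_sites(np.flatnonzero(keep)), report


def filter_mac(g: GenotypeMatrix, min_mac: int = 5):
    """Drop sites with minor allele count strictly below ``min_mac``."""
    if min_mac < 1:
        raise ValueError("min_mac must be >= 1")
    keep = g.mac() >= min_mac
    report = FilterReport(n_input_sites=g.n_sites,
                          n_removed_mac=int((~keep).sum()),
                          n_retained=int(keep.sum()))
    return g.take_sites(np.flatnonzero(keep)), report


def _pair_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over joint calls.

    Composite (genotypic) LD: appropriate for unphased data. Fewer than three
    joint calls, or a monomorphic vector, yields 0 (cannot assess).
    """
    joint = (d1 != MISSING) & (d2 != MISSING)
    if joint.sum() < 3:
        return 0.0
    x = d1[joint].astype(np.float64)
    y = d2[joint].astype(np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 25_000):
    """Windowed LD pruning: among same-contig pairs within ``window_bp`` with
    r^2 above ``r2_max``, greedily drop the lower-MAF member (ties keep the
    earlier position) until no violating pair remains."""
    maf = g.maf()
    alive = np.ones(g.n_sites, dtype=bool)
    chrom = g.chrom
    pos = g.pos
    for i in range(g.n_sites):
        if not alive[i]:
            continue
        j = i + 1
        while j < g.n_sites and chrom[j] == chrom[i] and pos[j] - pos[i] <= window_bp:
            if alive[j] and alive[i]:
                r2 = _pair_r2(g.dosages[:, i], g.dosages[:, j])
                if r2 > r2_max:
                    # keep the higher-MAF site; on ties keep the earlier one
                    if maf[j] > maf[i]:
                        alive[i] = False
                    else:
                        alive[j] = False
            j += 1
            if not alive[i]:
                break
    report = FilterReport(n_input_sites=g.n_sites,
                          n_removed_ld=int((~alive).sum()),
                          n_retained=int(alive.sum()))
    return g.take_sites(np.flatnonzero(alive)), report


def apply_default_filters(g: GenotypeMatrix, min_rate: float = 0.8,
                          min_mac: int = 5, r2_max: float = 0.2,
                          window_bp: int = 25_000):
    """Call-rate -> MAC -> LD pruning, with a combined :class:`FilterReport`."""
    g1, r1 = filter_call_rate(g, min_rate)
    g2, r2 = filter_mac(g1, min_mac)
    g3, r3 = ld_prune(g2, r2_max, window_bp)
    report = FilterReport(
        n_input_sites=g.n_sites,
        n_removed_call_rate=r1.n_removed_call_rate,
        n_removed_mac=r2.n_removed_mac,
        n_removed_ld=r3.n_removed_ld,
        n_retained=g3.n_sites)
    return g3, report
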