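"""Synthetic study bundles with known demographic truth.

Generates everything the pipeline consumes — a diploid genotype matrix (and
VCF) sampled from the two-deme best-fit history, per-individual coordinates
with a north-south gradient (admixed individuals geographically and
genetically intermediate: one haplotype from each deme), sampling years
across a 25-year span, slope and land-use rasters, a bioclim-style climate
table whose variables track latitude, and a minority of planted
high-differentiation outlier loci — plus a ``truth`` record sufficient to
regenerate the bundle bit-identically.

Planted outliers are drawn from a variant history with the divergence time
multiplied by ``outlier_factor`` and migration switched off, which mimics a
locus under divergent selection without modelling selection in the
coalescent itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import DemographicModel, Epoch, simulate_haplotypes
from .genotypes import GenotypeMatrix, write_vcf
from .landscape import Raster
from .scenarios import BEST_FIT_PARAMS, best_fit_model

__all__ = ["StudyBundle", "generate_study", "regenerate", "planar_coords"]

# generator defaults: ~71 individuals like the empirical sampling design
N_PER_POP = 23
N_ADMIX = 25
SPAN_YEARS = 25
LAST_YEAR = 2023
OUTLIER_FACTOR = 6.0

#: climate analogues emitted by the generator (diurnal range, temperature
#: seasonality, annual range, driest-month precipitation, precip seasonality)
CLIMATE_VARS = ("bio2", "bio4", "bio7", "bio14", "bio15")

_LON0, _LAT0 = 120.0, 21.8   # planar origin of the synthetic rasters
_M_PER_DEG_LAT = 110_540.0
_M_PER_DEG_LON = 102_470.0   # at ~23.5 degrees N


def planar_coords(lon, lat):
    """Equirectangular projection onto the synthetic raster plane (m)."""
    return ((np.asarray(lon) - _LON0) * _M_PER_DEG_LON,
            (np.asarray(lat) - _LAT0) * _M_PER_DEG_LAT)


@dataclass
class StudyBundle:
    genotypes: GenotypeMatrix
    sites: pd.DataFrame          # site_id, lon, lat, x, y, year, pop_label
    slope: Raster
    landuse: Raster
    climate: pd.DataFrame        # indexed by site_id
    truth: dict

    def write(self, outdir) -> dict:
        """Write VCF, CSVs, rasters and truth.json; returns file hashes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.genotypes, outdir / "genotypes.vcf")
        self.sites.to_csv(outdir / "sites.csv", index=False)
        self.climate.to_csv(outdir / "climate.csv")
        self.slope.to_ascii(outdir / "slope.asc")
        self.landuse.to_ascii(outdir / "landuse.asc")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True))
        hashes = {}
        for f in sorted(outdir.iterdir()):
            hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        return hashes


def _outlier_variant(model: DemographicModel, factor: float, n_loci: int
                     ) -> DemographicModel:
    epochs = [Epoch(e.start_time, e.sizes, np.zeros((2, 2)))
              for e in model.epochs]
    return DemographicModel(
        model.sample_sizes, epochs, model.divergence_time * factor,
        model.n_anc, model.mutation_rate, model.locus_length, n_loci,
        model.size_units)


def generate_study(seed: int, model: DemographicModel | None = None,
                   n_per_pop: int = N_PER_POP, n_admix: int = N_ADMIX,
                   n_loci: int = 2000, outliers: int = 20,
                   outlier_factor: float = OUTLIER_FACTOR) -> StudyBundle:
    """Generate a complete synthetic study bundle.

    ``n_per_pop`` diploids per source population plus ``n_admix`` admixed
    individuals (one haplotype from each deme). ``outliers`` of the
    ``n_loci`` loci are re-drawn under the elevated-divergence, no-flow
    variant and recorded in ``truth``. Deterministic in ``seed``.
    """
    n_hap = 2 * n_per_pop + n_admix          # haploids needed per deme
    custom_model = model is not None
    if model is None:
        model = best_fit_model(sample_sizes=(n_hap, n_hap), n_loci=n_loci)
    else:
        model = DemographicModel(
            (n_hap, n_hap), model.epochs, model.divergence_time, model.n_anc,
            model.mutation_rate, model.locus_length, n_loci,
            model.size_units)
    ss = np.random.SeedSequence(int(seed))
    seeds = ss.generate_state(8) % (2 ** 31)

    neutral = DemographicModel(
        model.sample_sizes, model.epochs, model.divergence_time, model.n_anc,
        model.mutation_rate, model.locus_length, n_loci - outliers,
        model.size_units)
    haps_n, chrom_n, pos_n = simulate_haplotypes(neutral, int(seeds[0]),
                                                 chrom_prefix="L")
    out_model = _outlier_variant(model, outlier_factor, outliers)
    haps_o, chrom_o, pos_o = simulate_haplotypes(out_model, int(seeds[1]),
                                                 chrom_prefix="OL")
    haps = np.concatenate([haps_n, haps_o], axis=1)
    chrom = np.concatenate([chrom_n, chrom_o])
    pos = np.concatenate([pos_n, pos_o])

    # diploid assembly: north pairs, south pairs, then cross-deme admixed
    n1 = model.sample_sizes[0]
    north = haps[:n1]
    south = haps[n1:]
    rows, labels = [], []
    for i in range(n_per_pop):
        rows.append(north[2 * i] + north[2 * i + 1])
        labels.append("north")
    for i in range(n_admix):
        rows.append(north[2 * n_per_pop + i] + south[2 * n_per_pop + i])
        labels.append("admix")
    for i in range(n_per_pop):
        rows.append(south[2 * i] + south[2 * i + 1])
        labels.append("south")
    dosages = np.array(rows, dtype=np.int8)
    ids = [f"{lab}_{i:03d}" for i, lab in enumerate(labels)]
    order = np.lexsort((pos, chrom.astype(str)))
    g = GenotypeMatrix(dosages[:, order], ids, labels, chrom[order],
                       pos[order],
                       np.array(["A"] * len(pos), dtype=object),
                       np.array(["T"] * len(pos), dtype=object))

    # coordinates: north at high latitude, south low, admixed intermediate
    rng = np.random.default_rng(int(seeds[2]))
    lat_bands = {"north": (24.1, 25.2), "admix": (23.3, 24.1),
                 "south": (22.0, 23.3)}
    lats = np.array([rng.uniform(*lat_bands[lab]) for lab in labels])
    lons = rng.uniform(120.6, 121.9, size=len(labels))
    years = rng.integers(LAST_YEAR - SPAN_YEARS + 1, LAST_YEAR + 1,
                         size=len(labels))
    x, y = planar_coords(lons, lats)
    sites = pd.DataFrame({"site_id": ids, "lon": lons, "lat": lats,
                          "x": x, "y": y, "year": years,
                          "pop_label": labels})

    # climate: latitude-tracking analogues with site-level noise
    crng = np.random.default_rng(int(seeds[3]))
    rel = (lats - 22.0) / 3.2           # 0 (far south) .. 1 (far north)
    climate = pd.DataFrame({
        "bio2": 9.0 + 1.5 * rel + crng.normal(0, 0.25, len(rel)),
        "bio4": 480 + 260 * rel + crng.normal(0, 35, len(rel)),
        "bio7": 14.0 + 6.0 * rel + crng.normal(0, 0.6, len(rel)),
        "bio14": 45 - 28 * rel + crng.normal(0, 4, len(rel)),
        "bio15": 55 + 30 * rel + crng.normal(0, 5, len(rel)),
    }, index=pd.Index(ids, name="site_id"))

    # rasters on the planar grid (5 km cells over the sampling region)
    rrng = np.random.default_rng(int(seeds[4]))
    nrow, ncol = 82, 41
    cell = 5000.0
    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    ridge = (35 * np.exp(-((jj - 18 - 6 * np.sin(ii / 11)) / 7.0) ** 2)
             * (0.6 + 0.4 * np.sin(ii / 5.5) ** 2))
    slope_vals = np.clip(ridge + rrng.gamma(2.0, 3.0, size=(nrow, ncol)),
                         0, 75)
    slope = Raster(slope_vals, cell, (0.0, 0.0))
    lu_codes = rrng.choice([1, 2, 3, 4, 5, 6], size=(nrow, ncol),
                           p=[0.55, 0.15, 0.05, 0.15, 0.03, 0.07])
    landuse = Raster(lu_codes.astype(float), cell, (0.0, 0.0))

    truth = {
        "generator": "demogscape.synth.generate_study",
        "version": 1,
        "seed": int(seed),
        "best_fit_truth": dict(BEST_FIT_PARAMS),
        "custom_model": custom_model,
        "n_per_pop": n_per_pop,
        "n_admix": n_admix,
        "n_loci": n_loci,
        "outliers": outliers,
        "outlier_factor": outlier_factor,
        "outlier_loci": sorted(set(chrom_o.tolist())),
        "mutation_rate": model.mutation_rate,
        "locus_length": model.locus_length,
    }
    return StudyBundle(g, sites, slope, landuse, climate, truth)


def regenerate(truth: dict) -> StudyBundle:
    """Rebuild a bundle bit-identically from its truth record."""
    if truth.get("generator") != "demogscape.synth.generate_study" or \
            truth.get("version") != 1:
        raise ValueError("unrecognized truth record version")
    if truth.get("custom_model"):
        raise ValueError("bundle was generated from a custom model; "
                         "regenerate it through the same model object")
    return generate_study(
        truth["seed"], n_per_pop=truth["n_per_pop"],
        n_admix=truth["n_admix"], n_loci=truth["n_loci"],
        outliers=truth["outliers"], outlier_factor=truth["outlier_factor"])
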