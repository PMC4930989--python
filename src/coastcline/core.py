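"""Core domain containers shared across the pipeline.

The coordinate convention throughout the package is decimal degrees with
negative values south/west.  Site index 0 is always the *southernmost*
site, i.e. the upstream end for a northward (Humboldt-like) mean flow, and
positive alongshore displacement means northward transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: genotype code for a missing call (STRUCTURE convention)
MISSING = -9

#: kilometres per degree of latitude (mean Earth radius)
KM_PER_DEG_LAT = 111.195

_EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate pairs (decimal degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class CoastGrid:
    """An ordered set of coastal sites along a (roughly) one-dimensional shore.

    ``latitudes`` must be strictly increasing so that index 0 is the
    southernmost (upstream) site.  ``spacing_km`` is the uniform alongshore
    spacing when the grid is synthetic; ``None`` for irregular field grids.
    """

    site_ids: tuple
    latitudes: np.ndarray
    longitudes: np.ndarray
    spacing_km: float | None = None

    def __post_init__(self):
        lat = np.asarray(self.latitudes, dtype=float)
        lon = np.asarray(self.longitudes, dtype=float)
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        object.__setattr__(self, "latitudes", lat)
        object.__setattr__(self, "longitudes", lon)
        if lat.ndim != 1 or len(self.site_ids) != lat.size or lon.size != lat.size:
            raise ValueError("site_ids, latitudes and longitudes must have equal length")
        if not np.all(np.isfinite(lat)):
            raise ValueError("latitudes must be finite")
        if lat.size > 1 and not np.all(np.diff(lat) > 0):
            raise ValueError("latitudes must be strictly increasing (index 0 = southernmost site)")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def uniform_spacing_km(self, rtol: float = 1e-6) -> float:
        """Alongshore spacing, requiring the grid to be regular."""
        if self.spacing_km is not None:
            return float(self.spacing_km)
        d = np.diff(self.latitudes) * KM_PER_DEG_LAT
        if d.size == 0:
            raise ValueError("grid has fewer than 2 sites")
        if not np.allclose(d, d[0], rtol=rtol, atol=1e-9):
            raise ValueError("grid spacing is not uniform")
        return float(d[0])

    def index_of(self, site_id: str) -> int:
        return self.site_ids.index(str(site_id))

    @classmethod
    def regular(cls, n_sites: int, spacing_km: float = 10.0, lat_south: float = -45.0,
                lon: float = -73.0, prefix: str = "s") -> "CoastGrid":
        """Build a regular synthetic grid running northwards from ``lat_south``."""
        if n_sites < 2:
            raise ValueError("need at least 2 sites")
        lats = lat_south + np.arange(n_sites) * spacing_km / KM_PER_DEG_LAT
        ids = tuple(f"{prefix}{i:03d}" for i in range(n_sites))
        return cls(ids, lats, np.full(n_sites, float(lon)), spacing_km=float(spacing_km))


@dataclass
class ConnectivityMatrix:
    """Site-by-site larval settlement probabilities.

    ``C[i, j]`` is the probability that a larva released at site ``i``
    settles at site ``j`` within one pelagic duration.  Rows may sum to
    less than 1; the deficit is larval loss offshore or out of the domain.
    """

    grid: CoastGrid
    C: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        n = self.grid.n_sites
        if C.shape != (n, n):
            raise ValueError(f"connectivity matrix must be {n}x{n}, got {C.shape}")
        if np.any(C < -1e-12) or np.any(C > 1 + 1e-12):
            raise ValueError("connectivity entries must lie in [0, 1]")
        rs = C.sum(axis=1)
        if np.any(rs > 1 + 1e-9):
            raise ValueError("connectivity row sums must not exceed 1")
        self.C = np.clip(C, 0.0, 1.0)

    @property
    def row_sums(self) -> np.ndarray:
        return self.C.sum(axis=1)


@dataclass
class LineageCline:
    """Per-site northern-lineage fraction, as model state or observation.

    When sampling counts are attached, ``f`` equals ``count_north / n``
    exactly.  ``source`` tags provenance: mitochondrial calls, mean nuclear
    assignment probabilities, or model output.
    """

    grid: CoastGrid
    f: np.ndarray
    n: np.ndarray | None = None
    count_north: np.ndarray | None = None
    source: str = "model"

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        if f.shape != (self.grid.n_sites,):
            raise ValueError("f must have one entry per grid site")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")
        self.f = np.clip(f, 0.0, 1.0)
        if (self.n is None) != (self.count_north is None):
            raise ValueError("n and count_north must be supplied together")
        if self.n is not None:
            n = np.asarray(self.n, dtype=int)
            c = np.asarray(self.count_north, dtype=int)
            if n.shape != f.shape or c.shape != f.shape:
                raise ValueError("counts must have one entry per site")
            if np.any(n < 1) or np.any(c < 0) or np.any(c > n):
                raise ValueError("require 0 <= count_north <= n and n >= 1")
            if not np.allclose(self.f, c / n, atol=1e-9):
                raise ValueError("f must equal count_north / n when counts are present")
            self.n, self.count_north = n, c


@dataclass(frozen=True)
class FitnessScenario:
    """A latitudinal step in relative fecundity between the two lineages.

    The locally favored lineage has net fecundity ``R``; the other has
    ``R * (1 - delta_w)``.  With the default orientation the northern
    lineage is favored at latitudes >= ``break_latitude`` (i.e. north of
    the break) and the southern lineage south of it.
    """

    break_latitude: float
    delta_w: float
    R: float = 1.0
    north_favored_north: bool = True

    def __post_init__(self):
        if not (0.0 <= self.delta_w < 1.0):
            raise ValueError("delta_w must lie in [0, 1)")
        if self.R <= 0:
            raise ValueError("R must be positive")

    def mirrored(self, grid: CoastGrid) -> "FitnessScenario":
        """Scenario for the latitude-mirrored grid with lineage labels swapped."""
        lo, hi = grid.latitudes[0], grid.latitudes[-1]
        return FitnessScenario(
            break_latitude=lo + hi - self.break_latitude,
            delta_w=self.delta_w, R=self.R,
            north_favored_north=self.north_favored_north,
        )


_VALID_MITOTYPES = ("N", "S", "U")


@dataclass
class GenotypeTable:
    """Individuals x biallelic loci, coded 0/1/2 copies of the reference allele.

    Missing genotypes are coded ``MISSING`` (-9).  Each individual carries a
    site label (with coordinates in ``site_coords``) and a mitotype in
    {"N", "S", "U"} where "U" is unknown.
    """

    individual_ids: tuple
    sites: tuple
    mitotypes: np.ndarray
    loci: tuple
    G: np.ndarray
    site_coords: Mapping[str, tuple] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.individual_ids = tuple(str(i) for i in self.individual_ids)
        self.sites = tuple(str(s) for s in self.sites)
        self.loci = tuple(str(l) for l in self.loci)
        self.mitotypes = np.asarray(self.mitotypes, dtype=object)
        G = np.asarray(self.G, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if G.shape != (n, L):
            raise ValueError(f"genotype matrix must be {n}x{L}, got {G.shape}")
        bad = ~np.isin(G, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be in {0, 1, 2, -9}")
        if len(self.sites) != n or self.mitotypes.shape != (n,):
            raise ValueError("sites and mitotypes must have one entry per individual")
        if not set(self.mitotypes) <= set(_VALID_MITOTYPES):
            raise ValueError(f"mitotypes must be in {_VALID_MITOTYPES}")
        self.G = G

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.G == MISSING

    def site_labels(self) -> tuple:
        """Distinct site labels in order of first appearance."""
        seen: dict = {}
        for s in self.sites:
            seen.setdefault(s, None)
        return tuple(seen)

    def subset(self, individuals: Sequence[int] | None = None,
               loci: Sequence[int] | None = None) -> "GenotypeTable":
        ii = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        jj = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeTable(
            individual_ids=tuple(self.individual_ids[i] for i in ii),
            sites=tuple(self.sites[i] for i in ii),
            mitotypes=self.mitotypes[ii],
            loci=tuple(self.loci[j] for j in jj),
            G=self.G[np.ix_(ii, jj)],
            site_coords=dict(self.site_coords),
            metadata=dict(self.metadata),
        )

    def allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Reference-allele frequency per locus over the given rows (NaN if no data)."""
        G = self.G if rows is None else self.G[rows]
        ok = G != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(ok, G, 0).sum(axis=0) / (2.0 * ok.sum(axis=0))
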