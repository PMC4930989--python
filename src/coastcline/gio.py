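"""Readers/writers for the pipeline's tabular formats, and genotype QC.

Formats
-------
Genotype CSV
    One row per individual: ``id,site,lat,lon,mitotype,<locus...>`` with
    genotypes 0/1/2 (copies of the reference allele), missing as -9 or NA.
STRUCTURE two-row
    Whitespace-delimited, two rows per individual: ``id site a1 ... aL``
    with alleles coded 1 (reference) / 2 (alternate) and -9 missing.
Connectivity TSV
    Header row of site ids; one row per source site, first column the
    source site id.
Observed-cline CSV
    ``site,lat,lon,n,count_north`` or ``site,lat,lon,mean_assign_north``
    (optionally with ``n``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, CoastGrid, ConnectivityMatrix, GenotypeTable, LineageCline

_META_COLS = ("id", "site", "lat", "lon", "mitotype")


class FormatError(ValueError):
    """Malformed input file (carries a line/row reference where possible)."""


# ---------------------------------------------------------------------------
# genotype tables


def write_genotypes(table: GenotypeTable, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(_META_COLS) + list(table.loci))
        for i, ind in enumerate(table.individual_ids):
            lat, lon = table.site_coords.get(table.sites[i], (np.nan, np.nan))
            w.writerow([ind, table.sites[i], lat, lon, table.mitotypes[i]]
                       + [int(g) for g in table.G[i]])


def read_genotypes(path, dialect: str = "csv", site_coords=None) -> GenotypeTable:
    """Parse a genotype file; ``dialect`` is ``"csv"`` or ``"structure_two_row"``."""
    if dialect == "csv":
        return _read_genotypes_csv(path)
    if dialect == "structure_two_row":
        return _read_genotypes_structure(path, site_coords=site_coords)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_genotypes_csv(path) -> GenotypeTable:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if tuple(h.strip() for h in header[:5]) != _META_COLS:
        raise FormatError(f"{path}:1: header must start with {','.join(_META_COLS)}")
    loci = tuple(h.strip() for h in header[5:])
    ids, sites, mitos, G, coords = [], [], [], [], {}
    for ln, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(f"{path}:{ln}: expected {len(header)} fields, got {len(row)}")
        ind, site = row[0], row[1]
        if ind in ids:
            raise FormatError(f"{path}:{ln}: duplicate individual id {ind!r}")
        ids.append(ind)
        sites.append(site)
        try:
            coords[site] = (float(row[2]), float(row[3]))
        except ValueError:
            coords[site] = (np.nan, np.nan)
        mito = row[4].strip() or "U"
        if mito not in ("N", "S", "U"):
            raise FormatError(f"{path}:{ln}: mitotype must be N, S or U, got {mito!r}")
        mitos.append(mito)
        g = []
        for col, tok in enumerate(row[5:], start=6):
            tok = tok.strip()
            if tok.upper() in ("NA", ""):
                g.append(MISSING)
                continue
            try:
                v = int(tok)
            except ValueError:
                raise FormatError(f"{path}:{ln}: field {col}: bad genotype {tok!r}") from None
            if v not in (0, 1, 2, MISSING):
                raise FormatError(f"{path}:{ln}: field {col}: genotype must be 0/1/2/-9")
            g.append(v)
        G.append(g)
    if not ids:
        raise FormatError(f"{path}: no individuals")
    return GenotypeTable(tuple(ids), tuple(sites), np.array(mitos, dtype=object),
                         loci, np.array(G, dtype=np.int64), site_coords=coords)


def write_genotypes_structure(table: GenotypeTable, path) -> None:
    """STRUCTURE-style two-row output (1 = reference allele, 2 = alternate)."""
    with Path(path).open("w") as fh:
        for i, ind in enumerate(table.individual_ids):
            row1, row2 = [], []
            for g in table.G[i]:
                if g == MISSING:
                    row1.append(-9)
                    row2.append(-9)
                else:
                    row1.append(1 if g >= 1 else 2)
                    row2.append(1 if g == 2 else 2)
            for alleles in (row1, row2):
                fh.write(" ".join([ind, table.sites[i]] + [str(a) for a in alleles]) + "\n")


def _read_genotypes_structure(path, site_coords=None) -> GenotypeTable:
    path = Path(path)
    lines = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    if len(lines) % 2:
        raise FormatError(f"{path}: odd number of rows for a two-row format")
    n_fields = len(lines[0])
    if n_fields < 3:
        raise FormatError(f"{path}:1: need id, site and at least one locus")
    ids, sites, G = [], [], []
    for k in range(0, len(lines), 2):
        r1, r2 = lines[k], lines[k + 1]
        ln = k + 1
        if len(r1) != n_fields or len(r2) != n_fields:
            raise FormatError(f"{path}:{ln}: ragged rows (loci count mismatch)")
        if r1[0] != r2[0] or r1[1] != r2[1]:
            raise FormatError(f"{path}:{ln}: the two rows of {r1[0]!r} disagree on id/site")
        if r1[0] in ids:
            raise FormatError(f"{path}:{ln}: duplicate individual id {r1[0]!r}")
        ids.append(r1[0])
        sites.append(r1[1])
        g = []
        for col, (a1, a2) in enumerate(zip(r1[2:], r2[2:]), start=3):
            try:
                a1, a2 = int(a1), int(a2)
            except ValueError:
                raise FormatError(f"{path}:{ln}: field {col}: non-integer allele") from None
            if a1 == MISSING or a2 == MISSING:
                g.append(MISSING)
            elif a1 in (1, 2) and a2 in (1, 2):
                g.append((a1 == 1) + (a2 == 1))
            else:
                raise FormatError(f"{path}:{ln}: field {col}: allele codes must be 1, 2 or -9")
        G.append(g)
    loci = tuple(f"L{j:04d}" for j in range(n_fields - 2))
    coords = dict(site_coords or {})
    return GenotypeTable(tuple(ids), tuple(sites), np.array(["U"] * len(ids), dtype=object),
                         loci, np.array(G, dtype=np.int64), site_coords=coords)


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    """Record of the two-stage missing-data filter."""

    loci_removed: dict = field(default_factory=dict)        # locus -> missing fraction
    individuals_removed: dict = field(default_factory=dict)  # id -> missing fraction
    n_retained_individuals: int = 0
    n_retained_loci: int = 0
    n_variable_loci: int = 0


def apply_qc(table: GenotypeTable, locus_missing_max: float = 0.50,
             indiv_missing_max: float = 0.25) -> tuple[GenotypeTable, QCReport]:
    """Two-stage missing-data filter, loci first.

    Loci with a missing fraction strictly greater than ``locus_missing_max``
    (computed over all individuals) are dropped first; individuals missing
    strictly more than ``indiv_missing_max`` of the *remaining* loci are
    dropped second.  Both thresholds are strict inequalities.
    """
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("empty genotype table")
    miss = table.missing_mask
    locus_frac = miss.mean(axis=0)
    keep_loci = np.nonzero(locus_frac <= locus_missing_max)[0]
    if keep_loci.size == 0:
        raise ValueError("QC removed every locus")
    report = QCReport(loci_removed={table.loci[j]: float(locus_frac[j])
                                    for j in np.nonzero(locus_frac > locus_missing_max)[0]})
    ind_frac = miss[:, keep_loci].mean(axis=1)
    keep_ind = np.nonzero(ind_frac <= indiv_missing_max)[0]
    report.individuals_removed = {table.individual_ids[i]: float(ind_frac[i])
                                  for i in np.nonzero(ind_frac > indiv_missing_max)[0]}
    out = table.subset(individuals=keep_ind, loci=keep_loci)
    report.n_retained_individuals = out.n_individuals
    report.n_retained_loci = out.n_loci
    report.n_variable_loci = count_variable_loci(out)
    return out, report


def count_variable_loci(table: GenotypeTable) -> int:
    """Loci carrying at least two distinct alleles among non-missing genotypes."""
    G, ok = table.G, ~table.missing_mask
    any_ref = ((G > 0) & ok).any(axis=0)     # genotype 1 or 2 implies a reference allele
    any_alt = ((G < 2) & ok).any(axis=0)     # genotype 0 or 1 implies an alternate allele
    return int((any_ref & any_alt).sum())


# ---------------------------------------------------------------------------
# connectivity matrices and clines


def write_connectivity(conn: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(conn.C, index=list(conn.grid.site_ids), columns=list(conn.grid.site_ids))
    with Path(path).open("w") as fh:
        fh.write("site\t" + "\t".join(conn.grid.site_ids) + "\n")
        for sid, row in zip(conn.grid.site_ids, df.to_numpy()):
            fh.write(sid + "\t" + "\t".join(format(v, ".12g") for v in row) + "\n")


def read_connectivity(path, grid: CoastGrid | None = None,
                      latitudes=None, longitudes=None) -> ConnectivityMatrix:
    """Load a connectivity TSV; invariants are enforced on construction.

    Site coordinates come from ``grid`` (labels must match) or from the
    ``latitudes``/``longitudes`` arrays; with neither, sites are placed on
    a nominal 10 km grid so the matrix can still be validated and used.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise FormatError(f"{path}: row and column site labels disagree")
    C = df.to_numpy(dtype=float)
    if grid is not None:
        if tuple(grid.site_ids) != ids:
            raise FormatError(f"{path}: site labels do not match the supplied grid")
    elif latitudes is not None:
        grid = CoastGrid(ids, latitudes,
                         longitudes if longitudes is not None else np.zeros(len(ids)))
    else:
        grid = CoastGrid.regular(len(ids), spacing_km=10.0)
        grid = CoastGrid(ids, grid.latitudes, grid.longitudes, spacing_km=10.0)
    if np.any(C < 0):
        raise FormatError(f"{path}: negative connectivity entries")
    if np.any(C.sum(axis=1) > 1 + 1e-9):
        raise FormatError(f"{path}: a row sums to more than 1")
    return ConnectivityMatrix(grid, C)


def write_observed_cline(cline: LineageCline, path) -> None:
    g = cline.grid
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        if cline.n is not None:
            w.writerow(["site", "lat", "lon", "n", "count_north"])
            for i, s in enumerate(g.site_ids):
                w.writerow([s, g.latitudes[i], g.longitudes[i],
                            int(cline.n[i]), int(cline.count_north[i])])
        else:
            w.writerow(["site", "lat", "lon", "mean_assign_north"])
            for i, s in enumerate(g.site_ids):
                w.writerow([s, g.latitudes[i], g.longitudes[i], format(cline.f[i], ".12g")])


def read_observed_cline(path) -> LineageCline:
    path = Path(path)
    df = pd.read_csv(path)
    need = {"site", "lat", "lon"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(need)}")
    df = df.sort_values("lat", kind="stable")
    grid = CoastGrid(tuple(df["site"].astype(str)), df["lat"].to_numpy(), df["lon"].to_numpy())
    if {"n", "count_north"} <= set(df.columns):
        n = df["n"].to_numpy(dtype=int)
        c = df["count_north"].to_numpy(dtype=int)
        if np.any(c > n) or np.any(c < 0) or np.any(n < 1):
            raise FormatError(f"{path}: require 0 <= count_north <= n and n >= 1")
        return LineageCline(grid, c / n, n=n, count_north=c, source="mitochondrial")
    if "mean_assign_north" in df.columns:
        f = df["mean_assign_north"].to_numpy(dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise FormatError(f"{path}: mean_assign_north outside [0, 1]")
        return LineageCline(grid, f, source="nuclear_assignment")
    raise FormatError(f"{path}: need either (n, count_north) or mean_assign_north")
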