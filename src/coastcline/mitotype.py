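"""In-silico SpeI restriction typing of COI sequences and cline assembly.

The two mitochondrial lineages differ at a SpeI recognition site (ACTAGT),
so a single digest diagnoses lineage membership.  ACTAGT is its own
reverse complement, so a single-strand substring search suffices.  Which
lineage carries the intact site is a required configuration choice — it is
an empirical property of the assay, not a convention — so every caller
must pass the cut -> lineage mapping explicitly.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import CoastGrid, LineageCline
from .synthetic import SPEI_SITE


@dataclass(frozen=True)
class MitotypeCall:
    """Digest outcome and resulting lineage for one sequence."""

    sequence_id: str
    cut: bool
    lineage: str  # "N" or "S"


def spei_digest(sequence: str) -> bool:
    """True iff the SpeI recognition site ACTAGT occurs in the sequence.

    Case-insensitive; ambiguity codes (N etc.) never match.  The site is
    palindromic, so the reverse complement need not be searched.
    """
    s = str(sequence).upper()
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
    return SPEI_SITE in s


def classify_mitotypes(fasta, cut_lineage: str) -> list[MitotypeCall]:
    """One SpeI call per FASTA record.

    ``cut_lineage`` ("N" or "S") names the lineage whose haplotype carries
    the intact recognition site; records without the site get the other
    label.  ``fasta`` may be a path or an iterable of SeqRecords.
    """
    if cut_lineage not in ("N", "S"):
        raise ValueError("cut_lineage must be 'N' or 'S'")
    uncut_lineage = "S" if cut_lineage == "N" else "N"
    records = SeqIO.parse(str(fasta), "fasta") if isinstance(fasta, (str, Path)) else fasta
    calls, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        cut = spei_digest(str(rec.seq))
        calls.append(MitotypeCall(rec.id, cut, cut_lineage if cut else uncut_lineage))
    return calls


def cline_from_calls(calls, site_of, grid: CoastGrid) -> LineageCline:
    """Per-site northern-lineage frequency from mitotype calls.

    ``site_of`` maps sequence id -> site label on ``grid``.  Sites with no
    typed individuals are dropped from the returned cline (with a warning),
    never imputed.
    """
    n = np.zeros(grid.n_sites, dtype=int)
    c = np.zeros(grid.n_sites, dtype=int)
    for call in calls:
        site = site_of[call.sequence_id]
        i = grid.index_of(site)
        n[i] += 1
        c[i] += call.lineage == "N"
    return _drop_empty(grid, n, c, source="mitochondrial")


def cline_from_assignments(assign_north, site_of, grid: CoastGrid) -> LineageCline:
    """Per-site mean northern assignment probability (nuclear cline).

    ``assign_north`` maps individual id -> probability of belonging to the
    northern nuclear cluster; the site mean stands in for the northern
    frequency, with the number of individuals retained as ``n``.
    """
    sums = np.zeros(grid.n_sites)
    n = np.zeros(grid.n_sites, dtype=int)
    for ind, p in assign_north.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"assignment probability for {ind!r} outside [0, 1]")
        i = grid.index_of(site_of[ind])
        sums[i] += p
        n[i] += 1
    keep = np.nonzero(n > 0)[0]
    if keep.size < grid.n_sites:
        dropped = [grid.site_ids[i] for i in range(grid.n_sites) if n[i] == 0]
        warnings.warn(f"sites with no individuals dropped from cline: {dropped}")
    sub = CoastGrid(tuple(grid.site_ids[i] for i in keep), grid.latitudes[keep],
                    grid.longitudes[keep], spacing_km=None)
    return LineageCline(sub, sums[keep] / n[keep], source="nuclear_assignment")


def _drop_empty(grid: CoastGrid, n: np.ndarray, c: np.ndarray, source: str) -> LineageCline:
    keep = np.nonzero(n > 0)[0]
    if keep.size == 0:
        raise ValueError("no typed individuals on any site")
    if keep.size < grid.n_sites:
        dropped = [grid.site_ids[i] for i in range(grid.n_sites) if n[i] == 0]
        warnings.warn(f"sites with no individuals dropped from cline: {dropped}")
    sub = CoastGrid(tuple(grid.site_ids[i] for i in keep), grid.latitudes[keep],
                    grid.longitudes[keep], spacing_km=None)
    return LineageCline(sub, c[keep] / n[keep], n=n[keep], count_north=c[keep], source=source)


def write_calls(calls, site_of, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "site", "cut", "lineage"])
        for call in calls:
            w.writerow([call.sequence_id, site_of.get(call.sequence_id, ""),
                        int(call.cut), call.lineage])
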