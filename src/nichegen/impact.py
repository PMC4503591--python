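"""Genetic-erosion accounting under projected range shifts.

Intersects ensemble probability surfaces with sampled population
coordinates to call each population persistent or extirpated, then
recomputes regional and global diversity on the survivors: haplotype and
lineage losses, private-allele losses, and retained allelic richness and
gene diversity. The rationale: for low-dispersal species on a decadal
horizon, diversity in persisting populations is a good proxy for future
global diversity — variants confined to extirpated populations are lost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nichegen.popgen import (
    GenotypeTable,
    HaplotypeCountTable,
    allele_stats,
)
from nichegen.projection import EnsemblePrediction

__all__ = ["ImpactReport", "classify_persistence", "diversity_at_risk"]


def classify_persistence(
    populations: pd.DataFrame,
    pred: EnsemblePrediction,
    threshold: float,
    max_radius_cells: int = 0,
) -> pd.DataFrame:
    """Persist/extirpated call per population from the ensemble surface.

    ``populations`` needs columns id, lon, lat. A population persists when
    the ensemble probability at its cell is >= ``threshold`` (inclusive).
    Populations outside the grid (or on an all-NaN cell) may fall back to
    the nearest valid cell within ``max_radius_cells``; beyond that, error.
    """
    grid = pred.grid
    rows = []
    for rec in populations.itertuples(index=False):
        lon, lat = float(rec.lon), float(rec.lat)
        if grid.contains(lon, lat):
            iy, ix = grid.cell_index(lon, lat)
            iy, ix = int(iy), int(ix)
        else:
            iy, ix = None, None
        if iy is None or not np.isfinite(pred.P[iy, ix]):
            iy, ix = _nearest_valid_cell(grid, pred.P, lon, lat, max_radius_cells)
            if iy is None:
                raise ValueError(
                    f"population {rec.id!r} outside prediction extent "
                    f"(no valid cell within {max_radius_cells} cells)"
                )
        p = float(pred.P[iy, ix])
        rows.append({"id": rec.id, "lon": lon, "lat": lat, "P": p,
                     "persists": p >= threshold})
    return pd.DataFrame(rows).set_index("id")


def _nearest_valid_cell(grid, P, lon, lat, max_radius_cells):
    # points beyond the grid must be within the radius of the nearest edge
    res = grid.resolution
    overshoot = max(
        0.0,
        (grid.west - lon) / res,
        (lon - grid.east) / res,
        (grid.south - lat) / res,
        (lat - grid.north) / res,
    )
    if overshoot > max_radius_cells:
        return None, None
    # clamp to the nearest in-grid cell, then spiral outwards
    ix0 = int(np.clip((lon - grid.west) / grid.resolution, 0, grid.nx - 1))
    iy0 = int(np.clip((lat - grid.south) / grid.resolution, 0, grid.ny - 1))
    for radius in range(max_radius_cells + 1):
        best = None
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if max(abs(dy), abs(dx)) != radius:
                    continue
                iy, ix = iy0 + dy, ix0 + dx
                if 0 <= iy < grid.ny and 0 <= ix < grid.nx and np.isfinite(P[iy, ix]):
                    d = dy * dy + dx * dx
                    if best is None or d < best[0]:
                        best = (d, iy, ix)
        if best is not None:
            return best[1], best[2]
    return None, None


@dataclass
class ImpactReport:
    """Ledger of genetic variation lost vs retained under a scenario."""

    scenario: str
    calls: dict[str, bool]  # population -> persists
    lost_haplotypes: dict[str, list[str]]  # marker -> labels
    retained_haplotypes: dict[str, list[str]]
    lost_lineages: dict[str, list[str]]  # marker -> lineage ids
    lost_private_alleles: dict[str, int]  # group -> count lost with the group
    full_stats: pd.DataFrame
    survivor_stats: pd.DataFrame | None
    extirpated: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "scenario": self.scenario,
            "calls": self.calls,
            "extirpated": self.extirpated,
            "lost_haplotypes": self.lost_haplotypes,
            "retained_haplotypes": self.retained_haplotypes,
            "lost_lineages": self.lost_lineages,
            "lost_private_alleles": self.lost_private_alleles,
            "full_stats": self.full_stats.reset_index().to_dict(orient="records"),
            "survivor_stats": (
                self.survivor_stats.reset_index().to_dict(orient="records")
                if self.survivor_stats is not None
                else None
            ),
        }
        return json.dumps(payload, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def diversity_at_risk(
    calls: pd.DataFrame | dict[str, bool],
    haplotypes: HaplotypeCountTable | None = None,
    genotypes: GenotypeTable | None = None,
    lineage_map: dict[str, dict[str, str]] | None = None,
    grouping: dict[str, list[str]] | None = None,
    scenario: str = "scenario",
) -> ImpactReport:
    """Account for the genetic diversity carried by extirpated populations.

    ``calls`` maps population -> persists (or is the output of
    :func:`classify_persistence`). ``lineage_map`` maps marker ->
    {haplotype -> lineage}; a lineage is lost iff every population carrying
    any of its haplotypes is extirpated. Private-allele losses are counted
    per group (default: per population) as the number of private alleles
    belonging to wholly-extirpated groups.
    """
    if isinstance(calls, pd.DataFrame):
        call_map = {str(i): bool(v) for i, v in calls["persists"].items()}
    else:
        call_map = {str(k): bool(v) for k, v in calls.items()}
    survivors = sorted(k for k, v in call_map.items() if v)
    extirpated = sorted(k for k, v in call_map.items() if not v)

    lost_haps: dict[str, list[str]] = {}
    kept_haps: dict[str, list[str]] = {}
    lost_lineages: dict[str, list[str]] = {}
    if haplotypes is not None:
        unknown = set(haplotypes.populations) - set(call_map)
        if unknown:
            raise ValueError(f"populations without persistence calls: {sorted(unknown)}")
        for marker in haplotypes.markers:
            carriers: dict[str, set[str]] = {}
            for pop in haplotypes.populations:
                for hap, c in haplotypes.pop_counts(pop, marker).items():
                    if c > 0:
                        carriers.setdefault(hap, set()).add(pop)
            kept = sorted(
                h for h, pops in carriers.items()
                if any(call_map[p] for p in pops)
            )
            lost = sorted(set(carriers) - set(kept))
            kept_haps[marker] = kept
            lost_haps[marker] = lost
            if lineage_map is not None:
                if marker not in lineage_map:
                    raise KeyError(f"lineage map missing marker {marker!r}")
                lmap = lineage_map[marker]
                missing = set(carriers) - set(lmap)
                if missing:
                    raise KeyError(
                        f"lineage map missing haplotypes {sorted(missing)} for {marker!r}"
                    )
                lineages = sorted(set(lmap[h] for h in carriers))
                lost_lineages[marker] = sorted(
                    lin
                    for lin in lineages
                    if all(
                        not call_map[p]
                        for h, pops in carriers.items()
                        if lmap[h] == lin
                        for p in pops
                    )
                )

    full_stats = None
    survivor_stats = None
    lost_private: dict[str, int] = {}
    if genotypes is not None:
        unknown = set(genotypes.populations) - set(call_map)
        if unknown:
            raise ValueError(f"populations without persistence calls: {sorted(unknown)}")
        groups = (
            grouping
            if grouping is not None
            else {p: [p] for p in genotypes.populations}
        )
        full_stats = allele_stats(genotypes, groups)
        surviving_groups = {
            g: [p for p in pops if call_map[p]]
            for g, pops in groups.items()
        }
        surviving_groups = {g: pops for g, pops in surviving_groups.items() if pops}
        if surviving_groups:
            survivor_data = genotypes.data[
                genotypes.data["population"].isin(survivors)
            ]
            survivor_stats = allele_stats(GenotypeTable(survivor_data), surviving_groups)
        for g, pops in groups.items():
            if all(not call_map[p] for p in pops):
                lost_private[g] = int(full_stats.loc[g, "A_private"])

    if full_stats is None:
        full_stats = pd.DataFrame()
    return ImpactReport(
        scenario=scenario,
        calls=call_map,
        lost_haplotypes=lost_haps,
        retained_haplotypes=kept_haps,
        lost_lineages=lost_lineages,
        lost_private_alleles=lost_private,
        full_stats=full_stats,
        survivor_stats=survivor_stats,
        extirpated=extirpated,
    )
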