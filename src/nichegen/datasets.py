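"""Packaged reference dataset: range-wide organelle haplotype survey.

Haplotype counts for the mitochondrial *cox3* gene (618 bp) and the
chloroplast *rbc*L–*rbc*S spacer region (527–537 bp) in 18 populations of
the warm-temperate, canopy-forming seaweed *Bifurcaria bifurcata*, sampled
from its southern range edge in southern Morocco to its northern edge in
Ireland (~8 individuals sequenced per population). Two phylogroups are
present: lineage A confined to the two southernmost populations, lineage B
everywhere else, separated by 3 (*cox3*) / 2 (*rbc*) substitutions.

Counts are stored exactly as published. One row (Tarfaya, *cox3*) is
internally inconsistent — the published diversity value cannot be
reproduced from the published counts — and is flagged via
``inconsistent_rows`` so exact regression checks can exclude it.
"""

from __future__ import annotations

import pandas as pd

from nichegen.popgen import HaplotypeCountTable

__all__ = ["reference_haplotype_counts", "REGIONS", "POPULATIONS"]

# site code -> (name, region, latitude, longitude)
POPULATIONS = {
    "TAR": ("Tarfaya", "S Morocco", 27.917, -12.950),
    "OUA": ("El Ouatia", "S Morocco", 28.400, -11.400),
    "ESS": ("Essaouira", "C Morocco", 31.500, -9.767),
    "BDO": ("El Beddouza", "C Morocco", 32.533, -9.267),
    "JAD": ("El Jadida", "C Morocco", 33.200, -8.583),
    "ODE": ("Odeceixe", "Iberia", 37.433, -8.783),
    "RIH": ("Ribeira de Ilhas", "Iberia", 38.983, -9.417),
    "VIA": ("Viana do Castelo", "Iberia", 41.683, -8.850),
    "LIR": ("Lires", "Iberia", 43.000, -9.250),
    "RCO": ("A Coruna", "Iberia", 43.367, -8.333),
    "POR": ("Porcia", "Iberia", 43.550, -6.867),
    "LAS": ("Lastres", "Iberia", 43.500, -5.267),
    "ZUM": ("Zumaya", "Iberia", 43.283, -2.267),
    "PSM": ("Piriac-sur-Mer", "Brittany & British Isles", 47.367, -2.550),
    "SBM": ("Saint-Briac-sur-Mer", "Brittany & British Isles", 48.633, -2.133),
    "PLY": ("Plymouth", "Brittany & British Isles", 50.300, -4.083),
    "COR": ("Clonakilty", "Brittany & British Isles", 51.583, -8.783),
    "GAL": ("Galway", "Brittany & British Isles", 53.133, -9.217),
}

REGIONS = {
    "Morocco": ["TAR", "OUA", "ESS", "BDO", "JAD"],
    "Europe": ["ODE", "RIH", "VIA", "LIR", "RCO", "POR", "LAS", "ZUM",
               "PSM", "SBM", "PLY", "COR", "GAL"],
}

_COX3 = {
    "TAR": {"A1": 7, "A2": 1},  # published H implies counts 6:1 (n=7)
    "OUA": {"A1": 8},
    "ESS": {"B1": 8},
    "BDO": {"B1": 7},
    "JAD": {"B1": 8},
    "ODE": {"B1": 8},
    "RIH": {"B1": 3, "B2": 5},
    "VIA": {"B1": 8},
    "LIR": {"B2": 8},
    "RCO": {"B1": 8},
    "POR": {"B1": 2, "B2": 6},
    "LAS": {"B1": 7},
    "ZUM": {"B1": 8},
    "PSM": {"B1": 7},
    "SBM": {"B1": 7},
    "PLY": {"B1": 8},
    "COR": {"B1": 8},
    "GAL": {"B1": 7},
}

_RBC = {
    "TAR": {"A1": 6},
    "OUA": {"A1": 8},
    "ESS": {"B1": 7, "B6": 1},
    "BDO": {"B1": 4, "B2": 4},
    "JAD": {"B1": 2, "B2": 6},
    "ODE": {"B1": 8},
    "RIH": {"B1": 8},
    "VIA": {"B1": 5, "B4": 3},
    "LIR": {"B2": 8},
    "RCO": {"B1": 8},
    "POR": {"B3": 6, "B4": 2},
    "LAS": {"B1": 4, "B5": 3},
    "ZUM": {"B1": 7},
    "PSM": {"B1": 8},
    "SBM": {"B1": 8},
    "PLY": {"B1": 7},
    "COR": {"B1": 7},
    "GAL": {"B1": 4, "B5": 4},
}

# substitution counts between haplotypes, from the published genealogies:
# lineage A and B centres separated by 3 (cox3) / 2 (rbc) changes; within-
# lineage variants one step from the central haplotype. rbc B1/B2/B5 differ
# by a pentanucleotide-repeat variant, scored as k=1 by default.
_K_COX3 = {
    ("A1", "A2"): 1,
    ("B1", "B2"): 1,
    ("A1", "B1"): 3,
    ("A1", "B2"): 4,
    ("A2", "B1"): 4,
    ("A2", "B2"): 5,
}

_K_RBC = {
    ("B1", "B2"): 1,
    ("B1", "B5"): 1,
    ("B2", "B5"): 2,
    ("B1", "B3"): 1,
    ("B1", "B4"): 1,
    ("B1", "B6"): 1,
    ("B3", "B4"): 2,
    ("B3", "B6"): 2,
    ("B4", "B6"): 2,
    ("B2", "B3"): 2,
    ("B2", "B4"): 2,
    ("B2", "B6"): 2,
    ("B5", "B3"): 2,
    ("B5", "B4"): 2,
    ("B5", "B6"): 2,
    ("A1", "B1"): 2,
    ("A1", "B2"): 3,
    ("A1", "B3"): 3,
    ("A1", "B4"): 3,
    ("A1", "B5"): 3,
    ("A1", "B6"): 3,
}

LINEAGES = {
    "cox3": {"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
    "rbc": {"A1": "A", "B1": "B", "B2": "B", "B3": "B", "B4": "B",
            "B5": "B", "B6": "B"},
}


def reference_haplotype_counts() -> HaplotypeCountTable:
    """The 18-population haplotype survey as a :class:`HaplotypeCountTable`.

    Counts are exactly as published; ``inconsistent_rows`` flags
    ``("TAR", "cox3")``, whose published diversity cannot be reproduced
    from the published counts.
    """
    rows = []
    for marker, table in (("cox3", _COX3), ("rbc", _RBC)):
        for code, counts in table.items():
            name, region, lat, lon = POPULATIONS[code]
            for hap, count in counts.items():
                rows.append(
                    {
                        "population": code,
                        "region": region,
                        "latitude": lat,
                        "marker": marker,
                        "haplotype": hap,
                        "count": count,
                    }
                )
    return HaplotypeCountTable(
        pd.DataFrame(rows),
        fragment_lengths={"cox3": 618, "rbc": 530},
        differences={"cox3": dict(_K_COX3), "rbc": dict(_K_RBC)},
        inconsistent_rows=frozenset({("TAR", "cox3")}),
    )


def reference_region_map() -> dict[str, str]:
    """Population code -> 'Morocco' | 'Europe' (5 vs 13 populations)."""
    return {code: region for region, codes in REGIONS.items() for code in codes}
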