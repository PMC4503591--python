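"""Marker-based diversity and differentiation statistics.

Organelle haplotypes: haplotype diversity H, nucleotide diversity pi, and
single-nucleotide-difference genealogical networks. Codominant diploid
markers (microsatellites): allelic richness, private alleles, Nei gene
diversity, observed heterozygosity, the Weir & Cockerham (1984) inbreeding
coefficient f with a permutation test, Weir & Cockerham theta (F_ST),
Jost's D_est and Nei's D_A chord-free distance.

All estimators use the small-sample ("unbiased") corrections conventional in
population-genetics software: H and pi carry n/(n-1); gene diversity carries
2n/(2n-1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeCountTable",
    "GenotypeTable",
    "haplotype_diversity",
    "nucleotide_diversity",
    "allele_stats",
    "fis",
    "fst_wc",
    "jost_dest",
    "nei_da",
    "haplotype_network",
    "pool_regions",
    "diversity_summary",
    "pairwise_divergence_matrix",
    "write_network_edgelist",
    "read_haplotype_tsv",
    "write_haplotype_tsv",
]


# ---------------------------------------------------------------------------
# Containers


@dataclass
class HaplotypeCountTable:
    """Haplotype counts per population and marker.

    ``counts`` columns: population, region, latitude, marker, haplotype,
    count. ``fragment_lengths`` maps marker -> alignment length L (bp);
    ``differences`` maps marker -> {(hap_i, hap_j): substitution count},
    stored once per unordered pair.
    """

    counts: pd.DataFrame
    fragment_lengths: dict[str, int] = field(default_factory=dict)
    differences: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    inconsistent_rows: frozenset = frozenset()

    def __post_init__(self) -> None:
        if (self.counts["count"] < 0).any():
            raise ValueError("haplotype counts must be non-negative")

    @property
    def populations(self) -> list[str]:
        return list(self.counts["population"].unique())

    @property
    def markers(self) -> list[str]:
        return list(self.counts["marker"].unique())

    def pop_counts(self, population: str, marker: str) -> dict[str, int]:
        sel = self.counts[
            (self.counts["population"] == population)
            & (self.counts["marker"] == marker)
        ]
        return dict(zip(sel["haplotype"], sel["count"].astype(int)))

    def k(self, marker: str, h1: str, h2: str) -> int:
        if h1 == h2:
            return 0
        d = self.differences.get(marker, {})
        if (h1, h2) in d:
            return d[(h1, h2)]
        if (h2, h1) in d:
            return d[(h2, h1)]
        raise KeyError(f"no difference count for pair ({h1}, {h2}) of {marker}")


@dataclass
class GenotypeTable:
    """Long-format diploid genotypes.

    ``data`` columns: population, locus, individual, allele1, allele2.
    Missing data are coded as None/NaN in both allele columns.
    """

    data: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.data["population"].unique())

    @property
    def loci(self) -> list[str]:
        return list(self.data["locus"].unique())

    def scored(self, population=None, locus=None) -> pd.DataFrame:
        sel = self.data
        if population is not None:
            pops = [population] if isinstance(population, str) else list(population)
            sel = sel[sel["population"].isin(pops)]
        if locus is not None:
            sel = sel[sel["locus"] == locus]
        return sel.dropna(subset=["allele1", "allele2"])

    def allele_freqs(self, population, locus: str) -> dict[str, float]:
        sel = self.scored(population, locus)
        alleles = pd.concat([sel["allele1"], sel["allele2"]])
        if alleles.empty:
            return {}
        freqs = alleles.value_counts(normalize=True)
        return dict(freqs)


# ---------------------------------------------------------------------------
# Haplotype statistics


def haplotype_diversity(counts) -> float:
    """Unbiased haplotype diversity H = n/(n-1) (1 - sum p_i^2)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                   dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(counts: dict[str, int], k_ij, L: float) -> float:
    """pi = n/(n-1) * sum_{i<j} 2 p_i p_j k_ij / L (per-site pairwise diversity).

    ``k_ij`` maps unordered haplotype pairs to substitution counts.
    """
    if L <= 0:
        raise ValueError("fragment length must be positive")
    haps = [h for h, c in counts.items() if c > 0]
    c = np.array([counts[h] for h in haps], dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    p = c / n
    total = 0.0
    for (i, hi), (j, hj) in itertools.combinations(enumerate(haps), 2):
        if (hi, hj) in k_ij:
            k = k_ij[(hi, hj)]
        elif (hj, hi) in k_ij:
            k = k_ij[(hj, hi)]
        else:
            raise KeyError(f"missing difference count for pair ({hi}, {hj})")
        total += 2.0 * p[i] * p[j] * k
    return float(n / (n - 1) * total / L)


# ---------------------------------------------------------------------------
# Microsatellite statistics


def _group_pops(grouping, table: GenotypeTable) -> dict[str, list[str]]:
    if grouping is None:
        return {p: [p] for p in table.populations}
    return {g: list(mem) for g, mem in grouping.items()}


def allele_stats(genotypes: GenotypeTable, grouping=None) -> pd.DataFrame:
    """Per-group A (mean alleles/locus), A' (private alleles), H_E, H_O.

    ``grouping`` maps group id -> list of populations; default is one group
    per population. Private alleles are counted against the rest of the whole
    dataset. H_E is the small-sample-corrected Nei gene diversity
    (2n/(2n-1))(1 - sum p^2) averaged over loci; H_O is the observed
    heterozygote fraction averaged over loci.
    """
    groups = _group_pops(grouping, genotypes)
    # allele incidence per group for private-allele accounting
    incidence: dict[str, set] = {}
    for g, pops in groups.items():
        sel = genotypes.scored(pops)
        incidence[g] = set(
            zip(
                pd.concat([sel["locus"], sel["locus"]]),
                pd.concat([sel["allele1"], sel["allele2"]]),
            )
        )
    rows = []
    for g, pops in groups.items():
        a_counts, he_vals, ho_vals = [], [], []
        for locus in genotypes.loci:
            sel = genotypes.scored(pops, locus)
            if sel.empty:
                warnings.warn(f"group {g}: locus {locus} has no scored individuals")
                continue
            alleles = pd.concat([sel["allele1"], sel["allele2"]])
            n = len(sel)  # diploid individuals
            p = alleles.value_counts(normalize=True).to_numpy()
            a_counts.append(alleles.nunique())
            he_vals.append((2 * n) / (2 * n - 1) * (1.0 - np.sum(p**2)))
            ho_vals.append(float((sel["allele1"] != sel["allele2"]).mean()))
        others = set().union(*(incidence[h] for h in groups if h != g)) if len(groups) > 1 else set()
        private = len(incidence[g] - others)
        rows.append(
            {
                "group": g,
                "A": float(np.mean(a_counts)),
                "A_private": private,
                "H_E": float(np.mean(he_vals)),
                "H_O": float(np.mean(ho_vals)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _wc_f_components(genotypes: GenotypeTable, pops) -> tuple[float, float]:
    """Sums of the Weir–Cockerham within-individual (c) and within-population
    (b) variance components over loci and alleles, for a single group."""
    sum_b = 0.0
    sum_c = 0.0
    for locus in genotypes.loci:
        sel = genotypes.scored(pops, locus)
        n = len(sel)
        if n < 2:
            continue
        alleles = pd.concat([sel["allele1"], sel["allele2"]])
        for allele in alleles.unique():
            p = float((alleles == allele).mean())
            het = float(
                (
                    ((sel["allele1"] == allele) ^ (sel["allele2"] == allele))
                ).mean()
            )
            b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * het)
            c = het / 2.0
            sum_b += b
            sum_c += c
    return sum_b, sum_c


def fis(
    genotypes: GenotypeTable,
    group,
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Weir & Cockerham (1984) multilocus inbreeding coefficient f.

    Returns ``(f, p_value)``. Significance is one-sided (heterozygote
    deficit): alleles are permuted among individuals within the group,
    per locus, and p is the fraction of permutations with f_perm >= f_obs
    (with the +1 continuity correction). ``p_value`` is None when
    ``permutations`` is 0. Raises on monomorphic groups (f undefined).
    """
    pops = [group] if isinstance(group, str) else list(group)
    sum_b, sum_c = _wc_f_components(genotypes, pops)
    denom = sum_b + sum_c
    if denom == 0.0:
        raise ValueError("F_IS undefined: group is monomorphic at every locus")
    f_obs = 1.0 - sum_c / denom
    if permutations <= 0:
        return f_obs, None
    rng = np.random.default_rng(seed)
    data = genotypes.scored(pops)
    exceed = 0
    for _ in range(permutations):
        rows = []
        for locus, sel in data.groupby("locus", sort=False):
            pool = np.concatenate([sel["allele1"].to_numpy(), sel["allele2"].to_numpy()])
            rng.shuffle(pool)
            half = len(sel)
            rows.append(
                pd.DataFrame(
                    {
                        "population": "perm",
                        "locus": locus,
                        "individual": np.arange(half),
                        "allele1": pool[:half],
                        "allele2": pool[half:],
                    }
                )
            )
        perm = GenotypeTable(pd.concat(rows, ignore_index=True))
        pb, pc = _wc_f_components(perm, ["perm"])
        if pb + pc == 0.0:
            continue
        if 1.0 - pc / (pb + pc) >= f_obs:
            exceed += 1
    p = (exceed + 1.0) / (permutations + 1.0)
    return f_obs, p


def fst_wc(genotypes: GenotypeTable, pop_pair: tuple[str, str]) -> float:
    """Weir & Cockerham theta for a pair of populations.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are summed over loci and alleles
    before the ratio theta = sum a / sum (a + b + c). Negative estimates are
    returned as computed.
    """
    p1, p2 = pop_pair
    r = 2
    sum_a = sum_bc = 0.0
    shared = False
    for locus in genotypes.loci:
        sels = [genotypes.scored(p, locus) for p in (p1, p2)]
        ns = np.array([len(s) for s in sels], dtype=float)
        if (ns < 1).any():
            continue
        shared = True
        n_bar = ns.mean()
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - np.sum(ns**2) / (r * n_bar)) / (r - 1)
        all_alleles = pd.concat(
            [pd.concat([s["allele1"], s["allele2"]]) for s in sels]
        ).unique()
        for allele in all_alleles:
            ps = np.array(
                [
                    float(
                        (pd.concat([s["allele1"], s["allele2"]]) == allele).mean()
                    )
                    for s in sels
                ]
            )
            hs = np.array(
                [
                    float((((s["allele1"] == allele) ^ (s["allele2"] == allele))).mean())
                    for s in sels
                ]
            )
            p_bar = np.sum(ns * ps) / (r * n_bar)
            s2 = np.sum(ns * (ps - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = np.sum(ns * hs) / (r * n_bar)
            a = (n_bar / n_c) * (
                s2
                - (1.0 / (n_bar - 1))
                * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2.0
            sum_a += a
            sum_bc += a + b + c
    if not shared:
        raise ValueError(f"populations {p1}, {p2} share no scored loci")
    if sum_bc == 0.0:
        return 0.0
    return float(sum_a / sum_bc)


def _dest_one_locus(p1: dict[str, float], p2: dict[str, float],
                    n1: float | None, n2: float | None, mode: str) -> float | None:
    alleles = sorted(set(p1) | set(p2))
    x = np.array([p1.get(a, 0.0) for a in alleles])
    y = np.array([p2.get(a, 0.0) for a in alleles])
    hs_raw = 1.0 - 0.5 * (np.sum(x**2) + np.sum(y**2))
    pbar = 0.5 * (x + y)
    ht_raw = 1.0 - np.sum(pbar**2)
    if mode == "parametric":
        hs, ht = hs_raw, ht_raw
    elif mode == "estimated":
        if n1 is None or n2 is None:
            raise ValueError("estimated mode needs sample sizes")
        n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
        hs = (2.0 * n_harm / (2.0 * n_harm - 1.0)) * hs_raw
        ht = ht_raw + hs / (4.0 * n_harm)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if hs >= 1.0:
        return None
    return float((ht - hs) / (1.0 - hs) * 2.0)  # n/(n-1) with n=2 demes


def jost_dest(
    freqs1: dict[str, dict[str, float]],
    freqs2: dict[str, dict[str, float]],
    mode: str = "parametric",
    sample_sizes: tuple[float, float] | None = None,
) -> float:
    """Jost's D for a population pair from per-locus allele frequencies.

    ``freqs1``/``freqs2`` map locus -> {allele: frequency}. ``parametric``
    mode uses the plain (H_T - H_S)/(1 - H_S) * n/(n-1) with n=2 demes;
    ``estimated`` applies the Nei–Chesser small-sample corrections to H_S and
    H_T (``sample_sizes`` = diploid individuals per population). The
    multilocus value is the harmonic mean of per-locus D over loci with
    D > 0 (0 if none are positive; loci with undefined D are skipped).
    """
    n1, n2 = sample_sizes if sample_sizes is not None else (None, None)
    values = []
    for locus in freqs1:
        if locus not in freqs2:
            continue
        d = _dest_one_locus(freqs1[locus], freqs2[locus], n1, n2, mode)
        if d is not None:
            values.append(d)
    if not values:
        raise ValueError("D_est undefined for every locus")
    if len(values) == 1:
        return float(values[0])
    # harmonic mean over loci; negatives clamp to 0 and any zero locus
    # drives the multilocus value to 0
    clamped = np.maximum(np.array(values), 0.0)
    if np.any(clamped == 0.0):
        return 0.0
    return float(len(clamped) / np.sum(1.0 / clamped))


def nei_da(
    freqs1: dict[str, dict[str, float]],
    freqs2: dict[str, dict[str, float]],
) -> float:
    """Nei's D_A = 1 - (1/r) sum_loci sum_alleles sqrt(x_i y_i)."""
    shared = [loc for loc in freqs1 if loc in freqs2]
    if not shared:
        raise ValueError("no shared loci")
    total = 0.0
    for locus in shared:
        x, y = freqs1[locus], freqs2[locus]
        total += sum(np.sqrt(x[a] * y[a]) for a in set(x) & set(y))
    return float(1.0 - total / len(shared))


# ---------------------------------------------------------------------------
# Haplotype networks


def haplotype_network(
    frequencies: dict[str, int],
    k_ij: dict[tuple[str, str], int],
) -> nx.Graph:
    """Minimum-spanning network of haplotypes with unit-difference edges.

    Sampled haplotypes become nodes (attribute ``frequency``, ``sampled``
    True); edges of the minimum-spanning network (ties in weight are kept as
    alternative links) are decomposed into single-nucleotide steps by
    inserting inferred, unsampled intermediate nodes (``sampled`` False).
    """
    haps = sorted(h for h, c in frequencies.items() if c > 0)
    g = nx.Graph()
    for h in haps:
        g.add_node(h, frequency=int(frequencies[h]), sampled=True)
    if len(haps) < 2:
        return g

    def dist(a, b):
        if (a, b) in k_ij:
            return k_ij[(a, b)]
        if (b, a) in k_ij:
            return k_ij[(b, a)]
        raise KeyError(f"missing difference count for pair ({a}, {b})")

    edges = sorted(
        ((dist(a, b), a, b) for a, b in itertools.combinations(haps, 2))
    )
    # Kruskal sweep keeping within-weight ties: all edges of a given weight
    # joining components distinct *before* that weight level are retained.
    comp = {h: h for h in haps}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    kept = []
    for _, level in itertools.groupby(edges, key=lambda e: e[0]):
        level = list(level)
        snapshot = {h: find(h) for h in haps}
        adds = [
            (w, a, b) for w, a, b in level if snapshot[a] != snapshot[b]
        ]
        kept.extend(adds)
        for _, a, b in adds:
            ra, rb = find(a), find(b)
            if ra != rb:
                comp[ra] = rb
    inferred = 0
    for w, a, b in kept:
        if w <= 1:
            g.add_edge(a, b)
            continue
        prev = a
        for step in range(1, w):
            inferred += 1
            node = f"inferred_{inferred}"
            g.add_node(node, frequency=0, sampled=False)
            g.add_edge(prev, node)
            prev = node
        g.add_edge(prev, b)
    return g


# ---------------------------------------------------------------------------
# Pooling and summaries


def pool_regions(table, region_map: dict[str, str]):
    """Pool populations into regions; statistics apply to the pooled table.

    For a :class:`HaplotypeCountTable`, counts are summed within region; for
    a :class:`GenotypeTable`, populations are relabelled to their region.
    """
    if isinstance(table, HaplotypeCountTable):
        unmapped = set(table.populations) - set(region_map)
        if unmapped:
            raise KeyError(f"unmapped populations: {sorted(unmapped)}")
        df = table.counts.copy()
        df["population"] = df["population"].map(region_map)
        pooled = (
            df.groupby(["population", "marker", "haplotype"], as_index=False)
            .agg(count=("count", "sum"), latitude=("latitude", "mean"))
        )
        pooled["region"] = pooled["population"]
        return HaplotypeCountTable(
            pooled[["population", "region", "latitude", "marker", "haplotype", "count"]],
            fragment_lengths=dict(table.fragment_lengths),
            differences={m: dict(d) for m, d in table.differences.items()},
        )
    if isinstance(table, GenotypeTable):
        unmapped = set(table.populations) - set(region_map)
        if unmapped:
            raise KeyError(f"unmapped populations: {sorted(unmapped)}")
        df = table.data.copy()
        df["population"] = df["population"].map(region_map)
        return GenotypeTable(df)
    raise TypeError("expected HaplotypeCountTable or GenotypeTable")


def pairwise_divergence_matrix(
    genotypes: GenotypeTable, mode: str = "parametric"
) -> pd.DataFrame:
    """Square population matrix with theta (F_ST) above and Jost's D_est
    below the diagonal — the conventional compact layout for survey tables."""
    pops = genotypes.populations
    out = pd.DataFrame(np.zeros((len(pops), len(pops))), index=pops, columns=pops)
    freqs = {
        p: {loc: genotypes.allele_freqs(p, loc) for loc in genotypes.loci}
        for p in pops
    }
    sizes = {
        p: np.mean([len(genotypes.scored(p, loc)) for loc in genotypes.loci])
        for p in pops
    }
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            out.loc[a, b] = fst_wc(genotypes, (a, b))  # upper triangle
            fa = {loc: fr for loc, fr in freqs[a].items() if fr}
            fb = {loc: fr for loc, fr in freqs[b].items() if fr}
            out.loc[b, a] = jost_dest(
                fa, fb, mode=mode,
                sample_sizes=(sizes[a], sizes[b]) if mode == "estimated" else None,
            )
    return out


def write_network_edgelist(path, network: nx.Graph) -> None:
    """Haplotype network as TSV: node1, node2 plus a node table appended as
    comment lines (#node, frequency, sampled)."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\n")
        for a, b in network.edges:
            fh.write(f"{a}\t{b}\n")
        for n, d in network.nodes(data=True):
            fh.write(f"#{n}\t{d.get('frequency', 0)}\t{d.get('sampled', True)}\n")


def write_haplotype_tsv(path, table: HaplotypeCountTable) -> None:
    """Counts as TSV (population, region, latitude, marker, haplotype, count)."""
    table.counts.to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path, fragment_lengths=None, differences=None) -> HaplotypeCountTable:
    df = pd.read_csv(path, sep="\t")
    required = {"population", "marker", "haplotype", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"haplotype TSV needs columns {sorted(required)}")
    for col, default in (("region", ""), ("latitude", np.nan)):
        if col not in df.columns:
            df[col] = default
    return HaplotypeCountTable(
        df[["population", "region", "latitude", "marker", "haplotype", "count"]],
        fragment_lengths=fragment_lengths or {},
        differences=differences or {},
    )


def diversity_summary(
    genotypes: GenotypeTable | None,
    haplotypes: HaplotypeCountTable | None,
    grouping=None,
    permutations: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group table mirroring a field survey summary: A, A', H_E, H_O,
    F_IS (with significance when ``permutations`` > 0), and per marker H and
    pi where difference matrices and fragment lengths are available."""
    rows: dict[str, dict] = {}
    if genotypes is not None:
        stats = allele_stats(genotypes, grouping)
        groups = _group_pops(grouping, genotypes)
        for g in stats.index:
            rows[g] = dict(stats.loc[g])
            try:
                f, p = fis(genotypes, groups[g], permutations=permutations, seed=seed)
                rows[g]["F_IS"] = f
                rows[g]["F_IS_p"] = p
            except ValueError:
                rows[g]["F_IS"] = np.nan
                rows[g]["F_IS_p"] = np.nan
    if haplotypes is not None:
        if grouping is None:
            hap_groups = {p: [p] for p in haplotypes.populations}
        else:
            hap_groups = {g: list(m) for g, m in grouping.items()}
        for g, pops in hap_groups.items():
            row = rows.setdefault(g, {})
            for marker in haplotypes.markers:
                counts: dict[str, int] = {}
                for p in pops:
                    for h, c in haplotypes.pop_counts(p, marker).items():
                        counts[h] = counts.get(h, 0) + c
                n = sum(counts.values())
                if n < 2 or len([c for c in counts.values() if c > 0]) < 1:
                    continue
                if len([c for c in counts.values() if c > 0]) == 1:
                    row[f"H_{marker}"] = 0.0
                    row[f"pi_{marker}"] = 0.0
                    continue
                row[f"H_{marker}"] = haplotype_diversity(counts)
                if marker in haplotypes.differences and marker in haplotypes.fragment_lengths:
                    row[f"pi_{marker}"] = nucleotide_diversity(
                        counts,
                        haplotypes.differences[marker],
                        haplotypes.fragment_lengths[marker],
                    )
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("group")
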