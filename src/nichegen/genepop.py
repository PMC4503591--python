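"""Minimal Genepop reader/writer for diploid multilocus genotypes.

Supports the common layout: title line, one locus name per line (or a
single comma-separated line), then ``Pop`` blocks of
``individual ,  aabbcc ddeeff ...`` rows with 2- or 3-digit allele codes.
Missing genotypes are all-zero codes. Individuals of a ``Pop`` block are
assigned to the population named after the block's first individual's
prefix (text before the last ``_``), or ``pop<k>`` when absent.
"""

from __future__ import annotations

import re

import pandas as pd

from nichegen.popgen import GenotypeTable

__all__ = ["read_genepop", "write_genepop"]


def write_genepop(path, table: GenotypeTable, title: str = "nichegen export",
                  digits: int = 3) -> None:
    loci = table.loci
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus + "\n")
        for pop in table.populations:
            fh.write("Pop\n")
            sel = table.data[table.data["population"] == pop]
            for ind, rows in sel.groupby("individual", sort=True):
                codes = []
                by_locus = {r.locus: r for r in rows.itertuples(index=False)}
                for locus in loci:
                    r = by_locus.get(locus)
                    if r is None or pd.isna(r.allele1) or pd.isna(r.allele2):
                        codes.append("0" * (2 * digits))
                    else:
                        a1, a2 = int(r.allele1), int(r.allele2)
                        if not (0 < a1 < 10**digits and 0 < a2 < 10**digits):
                            raise ValueError(
                                f"allele code out of range for {digits}-digit genepop"
                            )
                        codes.append(f"{a1:0{digits}d}{a2:0{digits}d}")
                name = ind if str(ind).startswith(f"{pop}_") else f"{pop}_{ind}"
                fh.write(f"{name} ,  " + " ".join(codes) + "\n")


def read_genepop(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError("not a genepop file: too short")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    if not loci or i == len(body):
        raise ValueError("not a genepop file: no loci or no Pop blocks")
    rows = []
    pop_idx = 0
    pop_name = None
    for line in body[i:]:
        if line.strip().lower() == "pop":
            pop_idx += 1
            pop_name = None
            continue
        if "," not in line:
            raise ValueError(f"malformed genotype line: {line!r}")
        name, geno = line.split(",", 1)
        name = name.strip()
        if pop_name is None:
            pop_name = name.rsplit("_", 1)[0] if "_" in name else f"pop{pop_idx}"
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"individual {name!r}: {len(codes)} genotypes for {len(loci)} loci"
            )
        for locus, code in zip(loci, codes):
            if not re.fullmatch(r"\d+", code) or len(code) % 2 != 0:
                raise ValueError(f"bad genotype code {code!r}")
            d = len(code) // 2
            a1, a2 = int(code[:d]), int(code[d:])
            rows.append(
                {
                    "population": pop_name,
                    "locus": locus,
                    "individual": name,
                    "allele1": str(a1) if a1 else None,
                    "allele2": str(a2) if a2 else None,
                }
            )
    return GenotypeTable(pd.DataFrame(rows))
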