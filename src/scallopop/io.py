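"""File formats: Genepop genotype tables, outline CSVs, ASCII PGM images,
distance-matrix CSVs.

Genepop dialect notes. Both locus-name dialects are read (one name per line,
or comma-separated on a single line); allele coding is 2- or 3-digit with
"00"/"000" per-allele missing codes; population names follow the common
convention of taking the label of the last individual before the next "Pop"
separator. ``write_genepop`` additionally records the population names in
the title line (``pops=a|b|...``); ``read_genepop`` uses that hint when
present so that a write/read round trip reproduces the table exactly, and
falls back to the last-individual convention on foreign files.

Coordinates in outline CSVs are pixels, origin top-left, x rightward, y
downward, one ``x,y`` row per point.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .fst import DistanceMatrix
from .genotypes import MISSING, GenotypeTable, Locus
from .outlines import OutlineShape

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_outline_csv",
    "write_outline_csv",
    "read_pgm",
    "write_pgm",
    "read_distance_csv",
    "write_distance_csv",
]


class GenepopParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def write_genepop(gt: GenotypeTable, path, title: str = "scallopop export") -> None:
    """Write a Genepop file; allele code width is 2 digits unless any allele
    code needs 3. Stored allele integers are written as code + 1 so that 0
    stays reserved for missing."""
    max_code = int(gt.calls.max(initial=0)) + 1
    width = 2 if max_code <= 99 else 3
    if max_code > 999:
        raise ValueError("allele codes exceed 3-digit Genepop coding")
    pops = gt.populations
    lines = [f"{title} ; pops={'|'.join(pops)}"]
    lines.extend(locus.id for locus in gt.loci)
    for pop in pops:
        lines.append("Pop")
        for i in gt.pop_indices(pop):
            codes = []
            for j in range(gt.n_loci):
                a, b = gt.calls[i, j]
                if a == MISSING:
                    codes.append("0" * (2 * width))
                else:
                    codes.append(f"{a + 1:0{width}d}{b + 1:0{width}d}")
            lines.append(f"{gt.individual_ids[i]} ,  " + " ".join(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path, snp_width_kinds: bool = True) -> GenotypeTable:
    """Read a Genepop file into a GenotypeTable.

    Locus kinds are inferred from the code width when ``snp_width_kinds`` is
    set: 2-digit files are treated as SNP panels only if every locus is
    biallelic, otherwise (and for 3-digit files) loci are microsatellites.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenepopParseError("empty file", 1)
    title = raw[0]
    m = re.search(r"pops=([^;]+)$", title.strip())
    pop_hint = m.group(1).split("|") if m else None

    locus_names: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        line = raw[i].strip()
        if line:
            if "," in line:
                locus_names.extend(s.strip() for s in line.split(",") if s.strip())
            else:
                locus_names.append(line)
        i += 1
    if not locus_names:
        raise GenepopParseError("no locus names before first Pop", i + 1)
    n_loci = len(locus_names)

    pops_rows: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    width = None
    for line_no in range(i, len(raw)):
        line = raw[line_no].strip()
        if not line:
            continue
        if line.lower() == "pop":
            if current is not None:
                pops_rows.append(current)
            current = []
            continue
        if current is None:
            raise GenepopParseError("genotype data before first Pop", line_no + 1)
        if "," not in line:
            raise GenepopParseError("individual line lacks a comma", line_no + 1)
        name, _, rest = line.partition(",")
        tokens = rest.split()
        if len(tokens) != n_loci:
            raise GenepopParseError(
                f"expected {n_loci} genotypes, found {len(tokens)}", line_no + 1
            )
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(f"malformed genotype {tok!r}", line_no + 1)
            w = len(tok) // 2
            if width is None:
                width = w
            elif width != w:
                raise GenepopParseError("mixed allele-code widths", line_no + 1)
        current.append((name.strip(), tokens))
    if current is not None:
        pops_rows.append(current)
    if not pops_rows:
        raise GenepopParseError("no populations found", len(raw))

    ids, labels, rows = [], [], []
    for k, pop in enumerate(pops_rows):
        if not pop:
            raise GenepopParseError("empty population block", 1)
        pname = pop_hint[k] if pop_hint and k < len(pop_hint) else pop[-1][0]
        for name, tokens in pop:
            ids.append(name)
            labels.append(pname)
            geno = []
            for tok in tokens:
                w = len(tok) // 2
                a, b = int(tok[:w]), int(tok[w:])
                if (a == 0) != (b == 0):
                    raise GenepopParseError(f"half-missing genotype {tok!r}", 1)
                geno.append((MISSING, MISSING) if a == 0 else (a - 1, b - 1))
            rows.append(geno)

    calls = np.array(rows, dtype=np.int64)
    kinds = ["microsat"] * n_loci
    if snp_width_kinds and width == 2:
        biallelic = all(
            np.unique(calls[:, j][calls[:, j] != MISSING]).size <= 2 for j in range(n_loci)
        )
        if biallelic:
            kinds = ["snp"] * n_loci
    loci = [Locus(nm, kd) for nm, kd in zip(locus_names, kinds)]
    return GenotypeTable(ids, labels, loci, calls)


# ---------------------------------------------------------------------------
# outlines and images


def write_outline_csv(outline: OutlineShape, path) -> None:
    pd.DataFrame(outline.points, columns=["x", "y"]).to_csv(path, index=False)


def read_outline_csv(path) -> OutlineShape:
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError("outline CSV needs 'x' and 'y' columns")
    return OutlineShape(df[["x", "y"]].to_numpy(dtype=float))


def write_pgm(image: np.ndarray, path, maxval: int = 255) -> None:
    """Plain (ASCII, P2) PGM; boolean masks are written as 0/maxval."""
    img = np.asarray(image)
    if img.dtype == bool:
        img = img.astype(int) * maxval
    h, w = img.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n{maxval}\n")
        for row in img:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_pgm(path) -> np.ndarray:
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise ValueError("only plain (P2) PGM files are supported")
    w, h, _maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4 : 4 + w * h], dtype=np.int64)
    return data.reshape(h, w)


# ---------------------------------------------------------------------------
# distance matrices


def write_distance_csv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(path)


def read_distance_csv(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))
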