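"""File I/O: ms-style haplotype text, per-locus FASTA, minimal VCF,
Newick trees and TSV tables.

Coordinate conventions: internal positions are 0-based fractions of
the locus length in [0, 1); VCF positions are 1-based.  Simulated data
is polarized (0 = ancestral); when reading VCFs the REF allele is
treated as ancestral, with an optional fold to minor-allele
frequencies (the f3 statistic is polarity-invariant).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from skbio import TreeNode

from .admixture import SnpFrequencyTable
from .containers import HaplotypeMatrix


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _opened(path_or_handle, mode: str):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


# ---------------------------------------------------------------------------
# ms-style text

def write_ms(loci: Sequence[HaplotypeMatrix], dest,
             header: str = "abcoal") -> None:
    """Write loci as ms-compatible text (//, segsites:, positions:, rows)."""
    fh, close = _opened(dest, "w")
    try:
        fh.write(f"{header}\n\n")
        for H in loci:
            fh.write("//\n")
            fh.write(f"segsites: {H.n_sites}\n")
            if H.n_sites:
                fh.write("positions: "
                         + " ".join(f"{p:.6f}" for p in H.positions) + "\n")
                for row in H.matrix:
                    fh.write("".join("1" if x else "0" for x in row) + "\n")
    finally:
        if close:
            fh.close()


def read_ms(src, nA: int, nB: int) -> List[HaplotypeMatrix]:
    """Parse ms-style text into haplotype matrices.

    The first ``nA`` haplotype rows of each locus are population A.
    Malformed input raises :class:`FormatError` with a line number.
    """
    fh, close = _opened(src, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    loci: List[HaplotypeMatrix] = []
    i = 0
    n = nA + nB
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise FormatError("expected 'segsites:' after '//'", i + 1)
        try:
            S = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise FormatError("unparsable segsites count", i + 1)
        i += 1
        if S == 0:
            loci.append(HaplotypeMatrix(np.zeros((n, 0), dtype=np.uint8),
                                        np.zeros(0), nA, nB,
                                        f"locus_{len(loci)}"))
            continue
        if i >= len(lines) or not lines[i].startswith("positions:"):
            raise FormatError("expected 'positions:' line", i + 1)
        pos = np.array([float(x) for x in lines[i].split()[1:]])
        if pos.size != S:
            raise FormatError(f"expected {S} positions, got {pos.size}", i + 1)
        i += 1
        rows = []
        for r in range(n):
            if i >= len(lines):
                raise FormatError(f"expected {n} haplotype rows, got {r}",
                                  i)
            row = lines[i].strip()
            if len(row) != S or set(row) - {"0", "1"}:
                raise FormatError("haplotype row must be 0/1 of length "
                                  f"{S}", i + 1)
            rows.append([int(ch) for ch in row])
            i += 1
        loci.append(HaplotypeMatrix(np.array(rows, dtype=np.uint8), pos,
                                    nA, nB, f"locus_{len(loci)}"))
    return loci


# ---------------------------------------------------------------------------
# FASTA (A/T pseudo-sequence encoding of 0/1)

def write_fasta(loci: Sequence[HaplotypeMatrix], dest) -> None:
    """One record per haplotype, 0 -> A (ancestral), 1 -> T (derived)."""
    fh, close = _opened(dest, "w")
    try:
        for H in loci:
            pop = ["A"] * H.nA + ["B"] * H.nB
            for i, row in enumerate(H.matrix):
                fh.write(f">{H.locus_id}|hap{i}|pop{pop[i]}\n")
                fh.write("".join("T" if x else "A" for x in row) + "\n")
    finally:
        if close:
            fh.close()


def read_fasta(src) -> List[HaplotypeMatrix]:
    """Inverse of :func:`write_fasta` (positions become uniform grid)."""
    fh, close = _opened(src, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    records: Dict[str, list] = {}
    pops: Dict[str, list] = {}
    name = None
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if line.startswith(">"):
            try:
                locus, _hap, pop = line[1:].split("|")
            except ValueError:
                raise FormatError("header must be >locus|hap|pop", ln)
            name = locus
            records.setdefault(locus, [])
            pops.setdefault(locus, []).append(pop)
        else:
            if name is None:
                raise FormatError("sequence before any header", ln)
            records[name].append([1 if c == "T" else 0 for c in line.strip()])
    loci = []
    for locus, rows in records.items():
        mat = np.array(rows, dtype=np.uint8)
        nA = sum(1 for p in pops[locus] if p == "popA")
        S = mat.shape[1]
        pos = (np.arange(S) + 0.5) / S if S else np.zeros(0)
        loci.append(HaplotypeMatrix(mat, pos, nA, mat.shape[0] - nA, locus))
    return loci


# ---------------------------------------------------------------------------
# minimal VCF (CHROM/POS/REF/ALT/GT)

def write_vcf(dest, chrom: Sequence[str], pos: Sequence[int],
              genotypes: np.ndarray, samples: Sequence[str],
              ref: str = "A", alt: str = "T") -> None:
    """Write a minimal biallelic VCF.

    ``genotypes`` is (n_snps, n_samples, 2) with 0 = REF, 1 = ALT and
    -1 = missing.  Positions are 1-based.
    """
    fh, close = _opened(dest, "w")
    gt = np.asarray(genotypes)
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in range(gt.shape[0]):
            cells = []
            for j in range(gt.shape[1]):
                a, b = gt[s, j]
                cells.append(("." if a < 0 else str(a)) + "/"
                             + ("." if b < 0 else str(b)))
            fh.write(f"{chrom[s]}\t{pos[s]}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


def snp_table_from_vcf(path: Union[str, Path],
                       pop_map: Mapping[str, str],
                       fold: bool = False) -> SnpFrequencyTable:
    """Population allele frequencies from a VCF's GT fields.

    The REF allele is treated as ancestral (ALT = derived); ``fold``
    switches to minor-allele frequencies computed over all samples.
    Missing genotype alleles are excluded per site (the haploid count
    varies by SNP), matching the listwise missing-data rule used for
    the summary statistics.
    """
    from cyvcf2 import VCF
    vcf = VCF(str(path), gts012=False)
    samples = vcf.samples
    pops = sorted(set(pop_map.values()))
    cols = {p: [i for i, s in enumerate(samples) if pop_map.get(s) == p]
            for p in pops}
    for p, c in cols.items():
        if not c:
            raise ValueError(f"population {p!r} has no samples in VCF")
    freq_rows, size_rows = [], []
    for var in vcf:
        gt = np.array(var.genotypes)[:, :2]  # (n_samples, 2), -1 missing
        if fold:
            valid_all = gt >= 0
            overall = gt[valid_all].mean() if valid_all.any() else 0.0
            flip = overall > 0.5
        freqs, sizes = [], []
        for p in pops:
            g = gt[cols[p]].ravel()
            g = g[g >= 0]
            nh = g.size
            if nh == 0:
                freqs.append(np.nan)
                sizes.append(0)
                continue
            f = g.mean()
            if fold and flip:
                f = 1.0 - f
            freqs.append(f)
            sizes.append(nh)
        freq_rows.append(freqs)
        size_rows.append(sizes)
    freq = pd.DataFrame(freq_rows, columns=pops)
    size = pd.DataFrame(size_rows, columns=pops)
    keep = freq.notna().all(axis=1) & (size >= 1).all(axis=1)
    return SnpFrequencyTable(freq[keep].reset_index(drop=True),
                             size[keep].reset_index(drop=True))


def write_snp_table(table: SnpFrequencyTable, dest) -> None:
    """Tidy TSV: snp, pop, freq, n (SNP order preserved)."""
    long = table.freq.stack().rename("freq").to_frame()
    long["n"] = table.size.stack()
    long.index.names = ["snp", "pop"]
    fh, close = _opened(dest, "w")
    try:
        long.reset_index().to_csv(fh, sep="\t", index=False)
    finally:
        if close:
            fh.close()


def read_snp_table(src) -> SnpFrequencyTable:
    df = pd.read_csv(src, sep="\t")
    freq = df.pivot(index="snp", columns="pop", values="freq").sort_index()
    size = df.pivot(index="snp", columns="pop", values="n").sort_index()
    return SnpFrequencyTable(freq.reset_index(drop=True),
                             size.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Newick and tables

def read_trees(src) -> Dict[str, TreeNode]:
    """One Newick tree per line; keys are locus_0, locus_1, ..."""
    fh, close = _opened(src, "r")
    try:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    finally:
        if close:
            fh.close()
    out = {}
    for i, line in enumerate(lines):
        try:
            out[f"locus_{i}"] = TreeNode.read(_io.StringIO(line))
        except Exception as exc:
            raise FormatError(f"unparsable Newick: {exc}", i + 1)
    return out


def write_trees(trees: Mapping[str, TreeNode], dest) -> None:
    fh, close = _opened(dest, "w")
    try:
        for tree in trees.values():
            fh.write(str(tree).strip() + "\n")
    finally:
        if close:
            fh.close()


def write_table(df: pd.DataFrame, dest) -> None:
    df.to_csv(dest, sep="\t", index=False)


def read_table(src) -> pd.DataFrame:
    return pd.read_csv(src, sep="\t")


def write_json(obj, dest) -> None:
    fh, close = _opened(dest, "w")
    try:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")
    finally:
        if close:
            fh.close()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
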