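"""Diagnostic-SNP allele-specific expression.

Re-implements the HyLiTE-style route to allelic counts: find positions
where the two parental RNA-seq pileups are each (near-)fixed for
different alleles, assign each hybrid read to the parent whose alleles
it carries at the diagnostic sites it covers, and aggregate assigned
reads into a gene x replicate allelic count matrix.

Pileups enter as tables (alignment itself is upstream of this package):
one row per covered position with per-base counts. Positions are 1-based
in pileup I/O, converted to 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import reverse_complement

__all__ = [
    "DiagnosticSNP",
    "AlleleAssignment",
    "pileup_from_sequence",
    "call_diagnostic_snps",
    "read_alleles",
    "assign_read",
    "allelic_counts",
]

_BASE_COLS = ["A", "C", "G", "T"]


@dataclass
class DiagnosticSNP:
    seq_id: str
    pos: int  # 0-based internal
    maternal: str
    paternal: str
    maternal_depth: int
    paternal_depth: int


@dataclass
class AlleleAssignment:
    read_id: str
    label: str  # maternal | paternal | unassigned
    n_mat_sites: int
    n_pat_sites: int
    reason: str  # consistent | conflict | no_sites


def pileup_from_sequence(sequence: str, seq_id: str = "chr1", depth: int = 20,
                         positions=None) -> pd.DataFrame:
    """Idealized pileup of a homozygous sample: every covered position shows
    ``depth`` copies of the reference base. ``positions`` (0-based) limits
    the table; the emitted ``pos`` column is 1-based per pileup convention."""
    if positions is None:
        positions = range(len(sequence))
    rows = []
    for p in positions:
        base = sequence[p].upper()
        row = {"seq_id": seq_id, "pos": p + 1, "A": 0, "C": 0, "G": 0, "T": 0}
        if base in _BASE_COLS:
            row[base] = depth
        rows.append(row)
    df = pd.DataFrame(rows, columns=["seq_id", "pos"] + _BASE_COLS)
    df["depth"] = df[_BASE_COLS].sum(axis=1)
    return df


def _major(df: pd.DataFrame):
    counts = df[_BASE_COLS].to_numpy()
    depth = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts.max(axis=1) / np.where(depth > 0, depth, 1)
    allele = np.array(_BASE_COLS)[counts.argmax(axis=1)]
    return allele, frac, depth


def call_diagnostic_snps(
    parent1_pileup: pd.DataFrame,
    parent2_pileup: pd.DataFrame,
    min_cov: int = 10,
    max_minor_fraction: float = 0.1,
) -> pd.DataFrame:
    """Fixed parental differences usable to assign hybrid reads.

    A position is diagnostic iff both parents have depth >= ``min_cov``,
    each parent's major allele carries >= 1 - max_minor_fraction of its
    depth (near-fixation), and the two major alleles differ. Parent 1 is
    taken as maternal. Returns a DataFrame with 0-based ``pos``.
    """
    merged = parent1_pileup.merge(
        parent2_pileup, on=["seq_id", "pos"], suffixes=("_1", "_2"), how="inner"
    )
    if merged.empty:
        import warnings

        warnings.warn("no shared pileup positions between parents")
        return pd.DataFrame(
            columns=["seq_id", "pos", "maternal", "paternal", "maternal_depth", "paternal_depth"]
        )
    a1, f1, d1 = _major(merged.rename(columns={f"{b}_1": b for b in _BASE_COLS}))
    a2, f2, d2 = _major(merged.rename(columns={f"{b}_2": b for b in _BASE_COLS}))
    purity = 1.0 - max_minor_fraction
    keep = (d1 >= min_cov) & (d2 >= min_cov) & (f1 >= purity) & (f2 >= purity) & (a1 != a2)
    out = pd.DataFrame(
        {
            "seq_id": merged["seq_id"][keep].to_numpy(),
            "pos": merged["pos"][keep].to_numpy() - 1,  # to 0-based
            "maternal": a1[keep],
            "paternal": a2[keep],
            "maternal_depth": d1[keep],
            "paternal_depth": d2[keep],
        }
    )
    return out.reset_index(drop=True)


def read_alleles(read_sequence: str, seq_id: str, start: int, strand: str,
                 diag: pd.DataFrame) -> list[tuple[int, str]]:
    """Observed bases of a gaplessly aligned read at the diagnostic sites it
    covers. ``start`` is the 0-based forward-strand start; minus-strand
    reads are reverse complements of the reference interval."""
    L = len(read_sequence)
    fwd = read_sequence if strand == "+" else reverse_complement(read_sequence)
    sub = diag[(diag["seq_id"] == seq_id) & (diag["pos"] >= start) & (diag["pos"] < start + L)]
    return [(int(p), fwd[int(p) - start]) for p in sub["pos"]]


def assign_read(observed: list[tuple[int, str]], diag: pd.DataFrame,
                read_id: str = "read", mode: str = "strict") -> AlleleAssignment:
    """Assign one hybrid read to a parental allele from its diagnostic-site
    bases.

    Strict (consensus) mode: every covered site must support the same
    parent; any conflict leaves the read unassigned. Majority mode
    assigns the parent with >50% of supporting sites (ties unassigned).
    Bases matching neither parental allele (or outside ACGT) are skipped.
    """
    if mode not in ("strict", "majority"):
        raise ValueError("mode must be 'strict' or 'majority'")
    lookup = {int(p): (m, f) for p, m, f in zip(diag["pos"], diag["maternal"], diag["paternal"])}
    n_mat = n_pat = 0
    for pos, base in observed:
        if pos not in lookup or base not in "ACGT":
            continue
        mat, pat = lookup[pos]
        if base == mat:
            n_mat += 1
        elif base == pat:
            n_pat += 1
    if n_mat == 0 and n_pat == 0:
        return AlleleAssignment(read_id, "unassigned", 0, 0, "no_sites")
    if mode == "strict":
        if n_mat > 0 and n_pat == 0:
            return AlleleAssignment(read_id, "maternal", n_mat, n_pat, "consistent")
        if n_pat > 0 and n_mat == 0:
            return AlleleAssignment(read_id, "paternal", n_mat, n_pat, "consistent")
        return AlleleAssignment(read_id, "unassigned", n_mat, n_pat, "conflict")
    if n_mat > n_pat:
        return AlleleAssignment(read_id, "maternal", n_mat, n_pat, "consistent")
    if n_pat > n_mat:
        return AlleleAssignment(read_id, "paternal", n_mat, n_pat, "consistent")
    return AlleleAssignment(read_id, "unassigned", n_mat, n_pat, "conflict")


def allelic_counts(
    assignments: pd.DataFrame,
    read_to_gene_overlaps: pd.DataFrame,
    gene_models: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-replicate allelic counts from read assignments.

    ``assignments``: read_id, replicate, label. ``read_to_gene_overlaps``:
    read_id, gene_id, overlap (bp). A read overlapping several genes
    counts once, toward the largest overlap (ties to the lowest gene id).
    Returns ``(matrix, summary)``: the matrix is long-form (gene_id,
    replicate, maternal, paternal); the summary gives assignment
    fractions over all reads.
    """
    known = set(gene_models["gene_id"])
    unknown = set(read_to_gene_overlaps["gene_id"]) - known
    if unknown:
        raise KeyError(f"unknown gene ids in overlaps: {sorted(unknown)[:5]}")

    best = (
        read_to_gene_overlaps.sort_values(
            ["read_id", "overlap", "gene_id"], ascending=[True, False, True]
        )
        .drop_duplicates("read_id")
        .set_index("read_id")["gene_id"]
    )
    df = assignments.copy()
    df["gene_id"] = df["read_id"].map(best)

    assigned = df[df["label"].isin(["maternal", "paternal"]) & df["gene_id"].notna()]
    tab = (
        assigned.groupby(["gene_id", "replicate", "label"], sort=True)
        .size()
        .unstack("label", fill_value=0)
        .reindex(columns=["maternal", "paternal"], fill_value=0)
        .reset_index()
    )
    tab.columns.name = None

    n = len(df)
    frac = df["label"].value_counts(normalize=True).reindex(
        ["maternal", "paternal", "unassigned"], fill_value=0.0
    )
    summary = pd.DataFrame(
        {
            "label": frac.index,
            "fraction": frac.to_numpy(),
            "n_reads": (frac * n).round().astype(int).to_numpy(),
        }
    )
    return tab, summary
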