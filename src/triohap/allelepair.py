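"""Haplotype allele pairing via homology and collinearity.

Defines the "allele pair" unit of haplotype-resolved ASE: a one-to-one
gene pair between the hybrid's maternal and paternal haplotypes that is
supported both by orthogroup membership (single-linkage components over
homology hits) and by collinear gene-block synteny (dynamic-programming
chaining of hit anchors in gene-rank space, MCScanX-style).

Homology hits come either from a precomputed 12-column tabular search
output or from the built-in affine-gap Smith-Waterman aligner (Biopython
``PairwiseAligner``), which is adequate at fixture scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CollinearBlock",
    "homology_hits",
    "parse_hit_table",
    "collinear_blocks",
    "orthogroups",
    "allele_pairs",
    "allelic_matrix_from_metagenome_counts",
]

HIT_COLUMNS = ["query", "subject", "score", "frac_aligned"]


def parse_hit_table(path, query_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Parse a standard 12-column tabular homology-search file
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore). Score = bitscore; aligned fraction = alignment
    length / query length when query lengths are known, else 1.0."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 12:
        raise ValueError(f"expected 12 columns, got {df.shape[1]}")
    out = pd.DataFrame(
        {
            "query": df[0].astype(str),
            "subject": df[1].astype(str),
            "score": df[11].astype(float),
            "frac_aligned": 1.0,
        }
    )
    if query_lengths:
        out["frac_aligned"] = [
            ln / query_lengths[q] if q in query_lengths else 1.0
            for q, ln in zip(out["query"], df[3].astype(float))
        ]
    return out


def _aligner(protein: bool):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aln = Align.PairwiseAligner()
    aln.mode = "local"
    if protein:
        aln.substitution_matrix = substitution_matrices.load("BLOSUM50")
        aln.open_gap_score = -8.0
        aln.extend_gap_score = -8.0
    else:
        aln.match_score = 2.0
        aln.mismatch_score = -3.0
        aln.open_gap_score = -5.0
        aln.extend_gap_score = -2.0
    return aln


def homology_hits(
    sequences_a: dict[str, str] | None = None,
    sequences_b: dict[str, str] | None = None,
    hit_file=None,
    protein: bool = True,
    min_score: float = 50.0,
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """All-vs-all similarity hits between two gene sets.

    Either a precomputed tabular hit file is passed through, or the
    built-in local aligner scores every pair (fixture scale only). Hits
    below ``min_score`` or aligned fraction below ``min_frac`` are
    dropped.
    """
    if hit_file is not None:
        hits = parse_hit_table(
            hit_file, {q: len(s) for q, s in (sequences_a or {}).items()} or None
        )
    elif sequences_a is not None and sequences_b is not None:
        aln = _aligner(protein)
        rows = []
        for qid, qseq in sequences_a.items():
            for sid, sseq in sequences_b.items():
                score = float(aln.score(qseq, sseq))
                if score <= 0:
                    continue
                best = aln.align(qseq, sseq)[0]
                qspan = best.aligned[0]
                alen = sum(e - s for s, e in qspan)
                rows.append(
                    {
                        "query": qid,
                        "subject": sid,
                        "score": score,
                        "frac_aligned": alen / len(qseq) if len(qseq) else 0.0,
                    }
                )
        hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    else:
        raise ValueError("supply either sequences for both sides or a hit file")
    keep = (hits["score"] >= min_score) & (hits["frac_aligned"] >= min_frac)
    return hits[keep].reset_index(drop=True)


@dataclass
class CollinearBlock:
    pairs: list[tuple[str, str]]  # (gene_a, gene_b) in chain order
    score: float
    orientation: str  # same | inverted
    block_id: int = 0


def _chain(anchors, max_gap: int, gap_penalty: float):
    """Best monotone increasing chain (both coordinates) over anchors
    ((ra, rb, score, idx) tuples sorted by ra then rb); O(n^2) DP."""
    n = len(anchors)
    best = [a[2] for a in anchors]
    prev = [-1] * n
    for i in range(n):
        ra_i, rb_i, s_i, _ = anchors[i]
        for j in range(i):
            ra_j, rb_j, _, _ = anchors[j]
            if ra_j >= ra_i or rb_j >= rb_i:
                continue
            gap = (ra_i - ra_j - 1) + (rb_i - rb_j - 1)
            if (ra_i - ra_j - 1) > max_gap or (rb_i - rb_j - 1) > max_gap:
                continue
            cand = best[j] + s_i - gap_penalty * gap
            if cand > best[i] or (cand == best[i] and prev[i] != -1 and j < prev[i]):
                best[i] = cand
                prev[i] = j
    if not n:
        return [], 0.0
    end = max(range(n), key=lambda i: (best[i], -anchors[i][0]))
    chain = []
    i = end
    while i != -1:
        chain.append(anchors[i])
        i = prev[i]
    chain.reverse()
    return chain, best[end]


def collinear_blocks(
    hits: pd.DataFrame,
    gene_models: pd.DataFrame,
    min_block: int = 5,
    max_gap: int = 25,
    gap_penalty: float = 1.0,
) -> list[CollinearBlock]:
    """Chain homology anchors into collinear (syntenic) gene blocks.

    Anchors are hits placed at the ordinal ranks of their two genes.
    Chains must be strictly monotone in rank on both sides (decreasing on
    one side for inverted blocks), with rank gaps <= ``max_gap``; chain
    score is the sum of hit scores minus a linear penalty per skipped
    rank. Maximal-scoring, anchor-disjoint chains of length >=
    ``min_block`` are reported greedily (best first).
    """
    ranks = gene_models.set_index("gene_id")["rank"].to_dict()
    anchors = []
    for idx, row in enumerate(hits.itertuples(index=False)):
        if row.query in ranks and row.subject in ranks:
            anchors.append((ranks[row.query], ranks[row.subject], float(row.score), idx))
    id_by_rank_a = {}
    id_by_rank_b = {}
    for row in hits.itertuples(index=False):
        if row.query in ranks:
            id_by_rank_a[ranks[row.query]] = row.query
        if row.subject in ranks:
            id_by_rank_b[ranks[row.subject]] = row.subject

    blocks: list[CollinearBlock] = []
    remaining = sorted(set(anchors), key=lambda a: (a[0], a[1]))
    max_rb = max((a[1] for a in remaining), default=0)
    while True:
        fwd = sorted(remaining, key=lambda a: (a[0], a[1]))
        chain_f, score_f = _chain(fwd, max_gap, gap_penalty)
        inv = sorted(
            [(ra, max_rb - rb, s, i) for ra, rb, s, i in remaining], key=lambda a: (a[0], a[1])
        )
        chain_r, score_r = _chain(inv, max_gap, gap_penalty)
        use_inverted = (len(chain_r) >= min_block) and (
            score_r > score_f or len(chain_f) < min_block
        )
        if use_inverted:
            chain = [(ra, max_rb - rb, s, i) for ra, rb, s, i in chain_r]
            score, orientation = score_r, "inverted"
        else:
            chain, score, orientation = chain_f, score_f, "same"
        if len(chain) < min_block:
            break
        pairs = [(id_by_rank_a[ra], id_by_rank_b[rb]) for ra, rb, _, _ in chain]
        blocks.append(CollinearBlock(pairs, score, orientation, block_id=len(blocks)))
        used = {(ra, rb) for ra, rb, _, _ in chain}
        remaining = [a for a in remaining if (a[0], a[1]) not in used]
        if not remaining:
            break
    return blocks


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def orthogroups(hits: pd.DataFrame, genes=None) -> dict[str, str]:
    """Gene -> orthogroup id by single-linkage transitive closure over
    hits. Group ids are ``OG_<smallest member gene id>``; genes with no
    hits form singletons (when listed in ``genes``)."""
    uf = _UnionFind()
    for row in hits.itertuples(index=False):
        uf.union(str(row.query), str(row.subject))
    members = set(map(str, hits["query"])) | set(map(str, hits["subject"]))
    if genes is not None:
        members |= set(map(str, genes))
    groups: dict[str, list[str]] = {}
    for g in members:
        groups.setdefault(uf.find(g), []).append(g)
    mapping = {}
    for root, gs in groups.items():
        og = f"OG_{min(gs)}"
        for g in gs:
            mapping[g] = og
    return mapping


def allele_pairs(
    blocks: list[CollinearBlock],
    orthogroup_map: dict[str, str],
    gene_models: pd.DataFrame,
) -> pd.DataFrame:
    """One-to-one maternal/paternal gene pairs supported by both synteny
    and orthogroup membership.

    A block pair (m, p) qualifies iff its orthogroup contains exactly one
    maternal and one paternal gene. Each gene appears in at most one
    output pair (first qualifying block wins).
    """
    hap = gene_models.set_index("gene_id")["haplotype"].to_dict()
    og_members: dict[str, list[str]] = {}
    for g, og in orthogroup_map.items():
        og_members.setdefault(og, []).append(g)

    rows = []
    used: set[str] = set()
    for block in blocks:
        for a, b in block.pairs:
            if a in used or b in used:
                continue
            og_a, og_b = orthogroup_map.get(a), orthogroup_map.get(b)
            if og_a is None or og_a != og_b:
                continue
            members = og_members[og_a]
            n_mat = sum(1 for g in members if hap.get(g) == "maternal")
            n_pat = sum(1 for g in members if hap.get(g) == "paternal")
            if n_mat != 1 or n_pat != 1:
                continue
            m, p = (a, b) if hap.get(a) == "maternal" else (b, a)
            if hap.get(m) != "maternal" or hap.get(p) != "paternal":
                continue
            rows.append(
                {
                    "maternal_gene": m,
                    "paternal_gene": p,
                    "block_id": block.block_id,
                    "orthogroup": og_a,
                }
            )
            used.update((a, b))
    return pd.DataFrame(rows, columns=["maternal_gene", "paternal_gene", "block_id", "orthogroup"])


def allelic_matrix_from_metagenome_counts(
    counts: pd.DataFrame, pairs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-pair count matrix from counts on the combined gene set.

    ``counts`` is indexed by haplotype-qualified gene ids (e.g.
    ``Hmat:g0001``) with one column per replicate — the result of mapping
    hybrid reads to the concatenated two-haplotype reference and keeping
    the best alignment. Returns a long allelic matrix (pair keyed by the
    maternal gene id) plus the counts of genes outside any pair.
    """
    known = set(pairs["maternal_gene"]) | set(pairs["paternal_gene"])
    unknown = [g for g in known if g not in counts.index]
    if unknown:
        raise KeyError(f"count table missing paired gene ids: {sorted(unknown)[:5]}")
    rows = []
    for row in pairs.itertuples(index=False):
        for rep in counts.columns:
            rows.append(
                {
                    "gene_id": row.maternal_gene,
                    "paternal_gene": row.paternal_gene,
                    "replicate": rep,
                    "maternal": int(counts.at[row.maternal_gene, rep]),
                    "paternal": int(counts.at[row.paternal_gene, rep]),
                }
            )
    matrix = pd.DataFrame(
        rows, columns=["gene_id", "paternal_gene", "replicate", "maternal", "paternal"]
    )
    unpaired = counts.loc[[g for g in counts.index if g not in known]]
    return matrix, unpaired
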