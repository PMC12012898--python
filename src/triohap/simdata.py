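"""Synthetic data for a hybrid-genome trio.

Emulates the study design this package targets: two divergent parental
haploid genomes, an F1 hybrid carrying one haplotype of each, short
sequencing reads with optional substitution errors, simple single-exon
gene models shared across haplotypes, and a 3x3 RNA-seq experiment
(two parents + hybrid, three replicates each) with planted heterosis
expression modes and allelic ratios.

Divergence is substitution-only by default so that coordinates are shared
between haplotypes and the variant table doubles as diagnostic-SNP truth.
Negative-binomial counts use the mean-dispersion parameterization
``var = mu + phi * mu**2``.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "MODE_NAMES",
    "SimConfig",
    "TruthTable",
    "SimRead",
    "simulate_parental_haplotypes",
    "simulate_reads",
    "make_gene_models",
    "simulate_rnaseq_counts",
    "simulate_bundle",
    "write_fixture_bundle",
    "parse_read_id",
    "reverse_complement",
]

MODE_NAMES = (
    "conserved",
    "additive",
    "high_parent_dominance",
    "low_parent_dominance",
    "overdominance",
    "underdominance",
)

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _default_mode_proportions() -> dict[str, float]:
    return {
        "conserved": 0.30,
        "additive": 0.30,
        "high_parent_dominance": 0.15,
        "low_parent_dominance": 0.05,
        "overdominance": 0.10,
        "underdominance": 0.10,
    }


@dataclass
class SimConfig:
    """Parameters of one simulated trio experiment.

    Defaults reproduce the study conditions this generator emulates: a
    hybrid whose haplotypes differ at ~4.6% of positions (the reported
    heterozygosity of the hybrid genome), 21-mers, three biological
    replicates per species, and four-fold planted expression effects.
    """

    genome_length: int = 100_000
    divergence: float = 0.046
    k: int = 21
    coverage: float = 30.0
    read_length: int = 150
    error_rate: float = 0.0
    n_genes: int = 60
    gene_length: int = 1_000
    replicates: int = 3
    dispersion: float = 0.05
    mode_proportions: dict[str, float] = field(default_factory=_default_mode_proportions)
    ase_ratio_grid: tuple[float, ...] = (0.2, 0.5, 0.8)
    effect_fold: float = 4.0
    base_mean_range: tuple[float, float] = (50.0, 800.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.k < 11 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 11")
        for name in ("genome_length", "read_length", "n_genes", "gene_length", "replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.genome_length < self.k:
            raise ValueError("genome too short for k")
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mode_proportions must sum to 1")
        unknown = set(self.mode_proportions) - set(MODE_NAMES)
        if unknown:
            raise ValueError(f"unknown expression modes: {sorted(unknown)}")
        for f in self.ase_ratio_grid:
            if not 0.0 <= f <= 1.0:
                raise ValueError("ase_ratio_grid values must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the top-level seed."""
        h = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:4], "big"))


@dataclass
class SimRead:
    id: str
    sequence: str
    quality: str


@dataclass
class TruthTable:
    """Ground truth for one simulated bundle."""

    variants: pd.DataFrame  # pos (0-based), maternal, paternal
    genes: pd.DataFrame  # gene_id, mode, parent1_mean, parent2_mean, hybrid_mean, maternal_fraction
    read_origins: pd.DataFrame | None = None  # read_id, haplotype, start, strand


def simulate_parental_haplotypes(config: SimConfig):
    """Two haploid sequences diverged from a common ancestor.

    Returns ``(maternal, paternal, variant_table)``. The maternal sequence
    is the ancestral one; the paternal carries a different base at each
    variant position, so realized divergence follows Binomial(L, d).
    Positions in the variant table are 0-based.
    """
    config.validate()
    rng = config.rng("haplotypes")
    ancestral = rng.integers(0, 4, size=config.genome_length)
    flip = rng.random(config.genome_length) < config.divergence
    pos = np.flatnonzero(flip)
    # shift by 1..3 in base space: always a different base
    paternal = ancestral.copy()
    paternal[pos] = (ancestral[pos] + rng.integers(1, 4, size=pos.size)) % 4
    maternal_seq = "".join(_BASES[ancestral])
    paternal_seq = "".join(_BASES[paternal])
    variant_table = pd.DataFrame(
        {
            "pos": pos,
            "maternal": _BASES[ancestral[pos]],
            "paternal": _BASES[paternal[pos]],
        }
    )
    return maternal_seq, paternal_seq, variant_table


def parse_read_id(read_id: str):
    """Invert the truth encoding of :func:`simulate_reads` identifiers."""
    label, start, strand, idx = read_id.split("|")
    return {"label": label, "start": int(start), "strand": strand, "index": int(idx)}


def simulate_reads(sequence: str, config: SimConfig, label: str = "hap",
                   coverage: float | None = None,
                   rng: np.random.Generator | None = None) -> list[SimRead]:
    """Uniform error-bearing short reads with truth-labeled identifiers.

    Identifier format ``label|start|strand|index`` with the 0-based start of
    the read on the forward strand; minus-strand reads are the reverse
    complement of the interval ``[start, start + read_length)``.
    """
    cov = config.coverage if coverage is None else coverage
    if cov <= 0:
        raise ValueError("coverage must be positive")
    L, rl = len(sequence), config.read_length
    if L < rl:
        raise ValueError("sequence shorter than read_length")
    if rng is None:
        rng = config.rng(f"reads:{label}")
    n_reads = int(round(cov * L / rl))
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    qual = "I" * rl
    reads: list[SimRead] = []
    for i in range(n_reads):
        s = int(starts[i])
        frag = sequence[s : s + rl]
        if config.error_rate > 0:
            arr = np.array(list(frag))
            err = rng.random(rl) < config.error_rate
            idx = np.flatnonzero(err)
            if idx.size:
                codes = np.searchsorted(_BASES, arr[idx])
                arr[idx] = _BASES[(codes + rng.integers(1, 4, size=idx.size)) % 4]
                frag = "".join(arr)
        strand = "-" if strands[i] else "+"
        if strand == "-":
            frag = reverse_complement(frag)
        reads.append(SimRead(f"{label}|{s}|{strand}|{i}", frag, qual))
    return reads


def make_gene_models(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping single-exon genes at identical coordinates on both
    haplotypes, evenly spaced along the genome."""
    span = config.genome_length // config.n_genes
    if span < config.gene_length:
        raise ValueError("genome too short for requested gene set")
    rows = []
    for i in range(config.n_genes):
        start = i * span
        rows.append(
            {
                "gene_id": f"g{i:04d}",
                "seq_id": "chr1",
                "start": start,
                "end": start + config.gene_length,
                "strand": "+",
                "rank": i,
            }
        )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2); phi == 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _plant_means(rng, mode: str, base: float, fold: float):
    """(parent1_mean, parent2_mean, hybrid_total_mean) for one gene."""
    if mode == "conserved":
        return base, base, base
    lo, hi = base, base * fold
    if rng.random() < 0.5:
        p1, p2 = lo, hi
    else:
        p1, p2 = hi, lo
    if mode == "additive":
        h = 0.5 * (lo + hi)
    elif mode == "high_parent_dominance":
        h = hi
    elif mode == "low_parent_dominance":
        h = lo
    elif mode == "overdominance":
        h = hi * fold
    elif mode == "underdominance":
        h = lo / fold
    else:  # pragma: no cover - guarded by SimConfig.validate
        raise ValueError(f"unknown mode {mode}")
    return p1, p2, h


def simulate_rnaseq_counts(config: SimConfig, variant_aware: bool = True):
    """Planted-truth RNA-seq counts for parents and hybrid.

    Returns ``(parent1_counts, parent2_counts, hybrid_allelic, truth)``.
    ``parent*_counts`` are gene x replicate integer DataFrames;
    ``hybrid_allelic`` is a long DataFrame (gene_id, replicate,
    maternal, paternal). Hybrid totals are NB draws around the planted
    mode's mean; maternal counts are Binomial(total, planted fraction).
    """
    config.validate()
    if config.dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = config.rng("rnaseq")
    n, reps, phi = config.n_genes, config.replicates, config.dispersion
    genes = [f"g{i:04d}" for i in range(n)]
    modes = rng.choice(
        list(config.mode_proportions), size=n, p=list(config.mode_proportions.values())
    )
    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    fracs = rng.choice(config.ase_ratio_grid, size=n)

    p1_mean = np.empty(n)
    p2_mean = np.empty(n)
    h_mean = np.empty(n)
    for i in range(n):
        p1_mean[i], p2_mean[i], h_mean[i] = _plant_means(rng, modes[i], base[i], config.effect_fold)

    cols = [f"rep{r+1}" for r in range(reps)]
    p1 = pd.DataFrame(
        {c: _nb_draw(rng, p1_mean, phi) for c in cols}, index=pd.Index(genes, name="gene_id")
    )
    p2 = pd.DataFrame(
        {c: _nb_draw(rng, p2_mean, phi) for c in cols}, index=pd.Index(genes, name="gene_id")
    )
    rows = []
    for r, c in enumerate(cols):
        total = _nb_draw(rng, h_mean, phi)
        if variant_aware:
            mat = rng.binomial(total, fracs)
        else:
            mat = rng.binomial(total, 0.5)
        for i, g in enumerate(genes):
            rows.append(
                {
                    "gene_id": g,
                    "replicate": c,
                    "maternal": int(mat[i]),
                    "paternal": int(total[i] - mat[i]),
                }
            )
    hybrid = pd.DataFrame(rows)
    truth = TruthTable(
        variants=pd.DataFrame(columns=["pos", "maternal", "paternal"]),
        genes=pd.DataFrame(
            {
                "gene_id": genes,
                "mode": modes,
                "parent1_mean": p1_mean,
                "parent2_mean": p2_mean,
                "hybrid_mean": h_mean,
                "maternal_fraction": fracs if variant_aware else np.full(n, 0.5),
            }
        ),
    )
    return p1, p2, hybrid, truth


@dataclass
class FixtureBundle:
    config: SimConfig
    maternal: str
    paternal: str
    variants: pd.DataFrame
    gene_models: pd.DataFrame
    maternal_reads: list[SimRead]
    paternal_reads: list[SimRead]
    hybrid_reads: list[SimRead]
    parent1_counts: pd.DataFrame
    parent2_counts: pd.DataFrame
    hybrid_allelic: pd.DataFrame
    truth: TruthTable


def simulate_bundle(config: SimConfig) -> FixtureBundle:
    """Run every generator stage once. Hybrid reads are drawn from each
    haplotype at half the configured depth (a diploid sequenced at
    ``coverage`` contributes coverage/2 per haplotype)."""
    mat, pat, variants = simulate_parental_haplotypes(config)
    gene_models = make_gene_models(config)
    mat_reads = simulate_reads(mat, config, label="mat")
    pat_reads = simulate_reads(pat, config, label="pat")
    hyb = simulate_reads(mat, config, label="hyb_mat", coverage=config.coverage / 2)
    hyb += simulate_reads(pat, config, label="hyb_pat", coverage=config.coverage / 2)
    p1, p2, allelic, truth = simulate_rnaseq_counts(config)
    truth.variants = variants
    origins = pd.DataFrame(
        [
            {
                "read_id": r.id,
                "haplotype": parse_read_id(r.id)["label"],
                "start": parse_read_id(r.id)["start"],
                "strand": parse_read_id(r.id)["strand"],
            }
            for r in hyb
        ]
    )
    truth.read_origins = origins
    return FixtureBundle(
        config=config,
        maternal=mat,
        paternal=pat,
        variants=variants,
        gene_models=gene_models,
        maternal_reads=mat_reads,
        paternal_reads=pat_reads,
        hybrid_reads=hyb,
        parent1_counts=p1,
        parent2_counts=p2,
        hybrid_allelic=allelic,
        truth=truth,
    )


def write_fixture_bundle(bundle: FixtureBundle, directory: str, overwrite: bool = False) -> pd.DataFrame:
    """Serialize a bundle to FASTA/FASTQ/GFF3/TSV and return a checksum manifest."""
    from . import io as tio

    if os.path.isdir(directory) and os.listdir(directory) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty (pass overwrite=True)")
    os.makedirs(directory, exist_ok=True)

    paths = {}
    paths["maternal.fasta"] = tio.write_fasta(
        {"Hmat_chr1": bundle.maternal}, os.path.join(directory, "maternal.fasta")
    )
    paths["paternal.fasta"] = tio.write_fasta(
        {"Hpat_chr1": bundle.paternal}, os.path.join(directory, "paternal.fasta")
    )
    for name, reads in (
        ("maternal_reads.fastq", bundle.maternal_reads),
        ("paternal_reads.fastq", bundle.paternal_reads),
        ("hybrid_reads.fastq", bundle.hybrid_reads),
    ):
        paths[name] = tio.write_fastq(reads, os.path.join(directory, name))
    paths["genes.gff3"] = tio.write_gff3(bundle.gene_models, os.path.join(directory, "genes.gff3"))
    for name, df in (
        ("variants.tsv", bundle.variants),
        ("parent1_counts.tsv", bundle.parent1_counts.reset_index()),
        ("parent2_counts.tsv", bundle.parent2_counts.reset_index()),
        ("hybrid_allelic.tsv", bundle.hybrid_allelic),
        ("truth_genes.tsv", bundle.truth.genes),
    ):
        p = os.path.join(directory, name)
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    config_path = os.path.join(directory, "config.tsv")
    cfg = asdict(bundle.config)
    pd.DataFrame(
        {"key": list(cfg), "value": [repr(v) for v in cfg.values()]}
    ).to_csv(config_path, sep="\t", index=False)
    paths["config.tsv"] = config_path

    rows = []
    for name, path in sorted(paths.items()):
        with open(path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        rows.append({"file": name, "sha256": digest})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(directory, "manifest.tsv"), sep="\t", index=False)
    return manifest
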