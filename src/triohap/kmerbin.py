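"""Trio binning and k-mer phasing QC.

Implements the k-mer machinery used to partition a hybrid's sequencing
reads by parental haplotype:

* canonical k-mer counting (numpy 2-bit rolling encoding),
* "solid" k-mer selection by a coverage window on the multiplicity
  histogram (auto-derived from the valley between the error peak and the
  main coverage peak when not given),
* hap-mer derivation: a parent's solid k-mers intersected with the
  hybrid's, minus the other parent's (the Merqury-style haplotype marker
  concept),
* exclusive-evidence read classification into maternal / paternal /
  ambiguous bins,
* phasing QC (hap-mer recovery, contamination, k-mer completeness, and a
  Phred-scaled assembly quality value), and
* telomere-motif run scanning.

Canonical form of a k-mer is the lexicographic minimum of the k-mer and
its reverse complement; with the A<C<G<T encoding used here this equals
the numeric minimum of the two 2-bit packed codes, so all set algebra is
done on sorted uint64 arrays.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import SimRead, reverse_complement

__all__ = [
    "KmerSet",
    "HapmerPair",
    "BinLabel",
    "PhasingQCReport",
    "TelomereRegion",
    "count_kmers",
    "solid_kmers",
    "derive_hapmers",
    "classify_read",
    "bin_reads",
    "phasing_qc",
    "find_telomere_repeats",
]

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.array(list("ACGT"))


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _canonical_codes(seq: str, k: int) -> np.ndarray:
    """Canonical packed codes of every valid k-mer window of ``seq``.

    Windows containing non-ACGT symbols are skipped. Output order follows
    the sequence; duplicates are retained.
    """
    b = _encode(seq)
    n = b.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    valid = b < 4
    ok = np.ones(m, dtype=bool)
    if not valid.all():
        # window valid iff all k bases valid: cumulative sum trick
        cs = np.concatenate(([0], np.cumsum(valid)))
        ok = (cs[k:] - cs[:-k]) == k
    bb = b.astype(np.uint64)
    bb[~valid] = 0  # placeholder; masked out via ok
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | bb[j : m + j]
        rev |= (np.uint64(3) - bb[j : m + j]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[ok]


def _decode_code(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


@dataclass
class KmerSet:
    """A set of canonical k-mers, optionally with multiplicities.

    ``codes`` is a sorted array of 2-bit packed canonical k-mers; when
    ``counts`` is present it is aligned with ``codes``.
    """

    k: int
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    counts: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        code = _canonical_codes(kmer, self.k)
        if code.size != 1:
            return False
        i = np.searchsorted(self.codes, code[0])
        return i < self.codes.size and self.codes[i] == code[0]

    def to_strings(self) -> list[str]:
        return [_decode_code(int(c), self.k) for c in self.codes]

    def multiplicity(self, kmer: str) -> int:
        if self.counts is None:
            raise ValueError("KmerSet has no multiplicities")
        code = _canonical_codes(kmer, self.k)
        if code.size != 1:
            return 0
        i = np.searchsorted(self.codes, code[0])
        if i < self.codes.size and self.codes[i] == code[0]:
            return int(self.counts[i])
        return 0

    def histogram(self) -> dict[int, int]:
        """Multiplicity -> number of distinct k-mers."""
        if self.counts is None:
            raise ValueError("KmerSet has no multiplicities")
        mult, n = np.unique(self.counts, return_counts=True)
        return {int(m): int(c) for m, c in zip(mult, n)}

    def drop_counts(self) -> "KmerSet":
        return KmerSet(self.k, self.codes.copy(), None)

    def _check(self, other: "KmerSet") -> None:
        if self.k != other.k:
            raise ValueError(f"k mismatch: {self.k} != {other.k}")

    def intersect(self, other: "KmerSet") -> "KmerSet":
        self._check(other)
        return KmerSet(self.k, np.intersect1d(self.codes, other.codes))

    def subtract(self, other: "KmerSet") -> "KmerSet":
        self._check(other)
        return KmerSet(self.k, np.setdiff1d(self.codes, other.codes))

    def union(self, other: "KmerSet") -> "KmerSet":
        self._check(other)
        return KmerSet(self.k, np.union1d(self.codes, other.codes))

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of packed codes."""
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, max(self.codes.size - 1, 0))
        if self.codes.size == 0:
            return np.zeros(codes.size, dtype=bool)
        return self.codes[idx] == codes


def count_kmers(sequences, k: int) -> tuple[KmerSet, dict[int, int]]:
    """Exact canonical k-mer counts over strings or read records.

    Accepts a single string, an iterable of strings, or an iterable of
    records with a ``sequence`` attribute. Returns the counted
    :class:`KmerSet` and its multiplicity histogram.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes canonicalization ambiguous)")
    if not 3 <= k <= 31:
        raise ValueError("k must be in [3, 31]")
    if isinstance(sequences, str):
        sequences = [sequences]
    chunks = []
    for s in sequences:
        seq = s.sequence if isinstance(s, SimRead) else getattr(s, "sequence", s)
        if not isinstance(seq, str):
            seq = str(seq)
        c = _canonical_codes(seq, k)
        if c.size:
            chunks.append(c)
    if not chunks:
        kset = KmerSet(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
        return kset, {}
    allc = np.concatenate(chunks)
    codes, counts = np.unique(allc, return_counts=True)
    kset = KmerSet(k, codes, counts.astype(np.int64))
    return kset, kset.histogram()


def _auto_window(hist: dict[int, int]) -> tuple[int, int]:
    """Coverage window from a k-mer histogram: low = the interior minimum
    between the error peak (multiplicity 1) and the main coverage peak,
    high = 4x the main peak multiplicity."""
    if not hist:
        raise ValueError("empty histogram; supply explicit solid-kmer thresholds")
    max_mult = max(hist)
    counts = np.zeros(max_mult + 1, dtype=np.int64)
    for m, c in hist.items():
        counts[m] = c
    # walk down from multiplicity 1 while counts decrease; the valley is
    # where they stop decreasing
    valley = None
    for m in range(2, max_mult):
        if counts[m] > counts[m - 1]:
            valley = m - 1
            break
    if valley is None or valley >= max_mult:
        raise ValueError(
            "histogram has no interior minimum between error and coverage peaks; "
            "supply explicit solid-kmer thresholds"
        )
    peak = valley + int(np.argmax(counts[valley:]))
    if peak == valley:
        raise ValueError(
            "no coverage peak beyond the valley; supply explicit solid-kmer thresholds"
        )
    return valley, 4 * peak


def solid_kmers(kmer_counts: KmerSet, low: int | None = None, high: int | None = None) -> KmerSet:
    """Select k-mers whose multiplicity lies in a coverage window.

    Solid k-mers are the error-filtered substrate of hap-mer derivation:
    multiplicities below ``low`` look like sequencing errors, above
    ``high`` like high-copy repeats. Omitted bounds are derived from the
    histogram; the returned set carries no multiplicities.
    """
    if kmer_counts.counts is None:
        raise ValueError("solid_kmers requires multiplicities")
    if low is not None and high is not None and low > high:
        raise ValueError("low > high")
    if low is None or high is None:
        auto_low, auto_high = _auto_window(kmer_counts.histogram())
        if low is None:
            low = auto_low
        if high is None:
            high = auto_high
    if low < 1:
        raise ValueError("low must be >= 1")
    mask = (kmer_counts.counts >= low) & (kmer_counts.counts <= high)
    return KmerSet(kmer_counts.k, kmer_counts.codes[mask], None)


@dataclass
class HapmerPair:
    """Disjoint maternal/paternal haplotype-marker k-mer sets."""

    maternal: KmerSet
    paternal: KmerSet

    def __post_init__(self) -> None:
        if self.maternal.k != self.paternal.k:
            raise ValueError("hap-mer sets must share k")
        if np.intersect1d(self.maternal.codes, self.paternal.codes).size:
            raise ValueError("hap-mer sets must be disjoint")

    @property
    def k(self) -> int:
        return self.maternal.k


def derive_hapmers(solid_maternal: KmerSet, solid_paternal: KmerSet, solid_hybrid: KmerSet) -> HapmerPair:
    """Haplotype markers: one parent's solid k-mers that the hybrid shares
    and the other parent lacks. Subtracting the other parent keeps the two
    sets disjoint, so shared sequence never votes for either haplotype."""
    if not (solid_maternal.k == solid_paternal.k == solid_hybrid.k):
        raise ValueError("k mismatch between solid sets")
    maternal = solid_maternal.intersect(solid_hybrid).subtract(solid_paternal)
    paternal = solid_paternal.intersect(solid_hybrid).subtract(solid_maternal)
    return HapmerPair(maternal, paternal)


@dataclass
class BinLabel:
    label: str  # maternal | paternal | ambiguous
    n_mat: int
    n_pat: int


def classify_read(read_sequence: str, hapmers: HapmerPair) -> BinLabel:
    """Exclusive-evidence trio binning of one read.

    A read is maternal iff at least one of its canonical k-mers is a
    maternal hap-mer and none is paternal (and symmetrically); reads
    hitting both sets or neither are ambiguous. Reads shorter than k are
    ambiguous with zero evidence.
    """
    codes = _canonical_codes(read_sequence, hapmers.k)
    if codes.size == 0:
        return BinLabel("ambiguous", 0, 0)
    codes = np.unique(codes)
    n_mat = int(hapmers.maternal.contains_codes(codes).sum())
    n_pat = int(hapmers.paternal.contains_codes(codes).sum())
    if n_mat > 0 and n_pat == 0:
        return BinLabel("maternal", n_mat, n_pat)
    if n_pat > 0 and n_mat == 0:
        return BinLabel("paternal", n_mat, n_pat)
    return BinLabel("ambiguous", n_mat, n_pat)


def bin_reads(read_stream, hapmers: HapmerPair):
    """Partition reads into maternal/paternal/ambiguous bins.

    Returns ``(bins, summary)`` where ``bins`` maps label -> list of
    records and ``summary`` is a one-row-per-bin DataFrame with counts
    and fractions. Unreadable records (no usable sequence) are skipped
    and counted.
    """
    bins: dict[str, list] = {"maternal": [], "paternal": [], "ambiguous": []}
    n_skipped = 0
    n_input = 0
    for rec in read_stream:
        n_input += 1
        seq = rec.sequence if hasattr(rec, "sequence") else rec
        if not isinstance(seq, str) or not seq:
            n_skipped += 1
            continue
        bins[classify_read(seq, hapmers).label].append(rec)
    rows = []
    for label in ("maternal", "paternal", "ambiguous"):
        n = len(bins[label])
        rows.append(
            {
                "bin": label,
                "n_reads": n,
                "fraction": n / n_input if n_input else 0.0,
            }
        )
    rows.append(
        {"bin": "skipped", "n_reads": n_skipped, "fraction": n_skipped / n_input if n_input else 0.0}
    )
    summary = pd.DataFrame(rows)
    return bins, summary


@dataclass
class PhasingQCReport:
    """Merqury-style phasing / base-accuracy metrics for one assembly.

    ``qv`` is the Phred-scaled per-base correctness derived from the
    fraction of assembly k-mers supported by the read set:
    P = fraction**(1/k), E = 1 - P, QV = -10*log10(E), capped at 99.
    """

    hapmer_recovery: float
    hapmer_contamination: float
    kmer_completeness: float
    qv: float
    p_correct: float
    error_rate: float
    degenerate: bool = False


QV_CAP = 99.0


def phasing_qc(
    assembly_sequence,
    hapmers: HapmerPair,
    read_solid: KmerSet,
    k: int,
    own: str = "maternal",
) -> PhasingQCReport:
    """Phasing and consensus QC of one haplotype assembly.

    ``own`` names the haplotype the assembly purports to represent.
    Recovery = % of own hap-mers present in the assembly; contamination =
    % of the hap-mers present (of either type) that belong to the other
    haplotype; completeness = % of the read-derived solid k-mers present.
    """
    if own not in ("maternal", "paternal"):
        raise ValueError("own must be 'maternal' or 'paternal'")
    if hapmers.k != k or read_solid.k != k:
        raise ValueError("k mismatch")
    asm_set, _ = count_kmers(assembly_sequence, k)
    if len(asm_set) == 0:
        return PhasingQCReport(0.0, 0.0, 0.0, 0.0, 0.0, 1.0, degenerate=True)
    asm = asm_set.drop_counts()

    own_set = hapmers.maternal if own == "maternal" else hapmers.paternal
    opp_set = hapmers.paternal if own == "maternal" else hapmers.maternal
    own_present = len(own_set.intersect(asm))
    opp_present = len(opp_set.intersect(asm))
    recovery = 100.0 * own_present / len(own_set) if len(own_set) else 0.0
    present_total = own_present + opp_present
    contamination = 100.0 * opp_present / present_total if present_total else 0.0

    completeness = (
        100.0 * len(read_solid.intersect(asm)) / len(read_solid) if len(read_solid) else 0.0
    )

    found = len(asm.intersect(read_solid))
    shared_fraction = found / len(asm)
    p = shared_fraction ** (1.0 / k)
    e = 1.0 - p
    qv = QV_CAP if e <= 0 else min(QV_CAP, -10.0 * np.log10(e))
    return PhasingQCReport(recovery, contamination, completeness, float(qv), float(p), float(e))


def qv_from_shared_fraction(shared_fraction: float, k: int) -> float:
    """QV implied by the fraction of assembly k-mers found in the reads."""
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    p = shared_fraction ** (1.0 / k)
    e = 1.0 - p
    return QV_CAP if e <= 0 else min(QV_CAP, float(-10.0 * np.log10(e)))


@dataclass
class TelomereRegion:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    n_repeats: int
    terminal: bool


def _motif_runs(sequence: str, motif: str, max_gap: int):
    """Maximal runs of motif copies with inter-copy gaps <= max_gap."""
    hits = [m.start() for m in re.finditer(f"(?={re.escape(motif)})", sequence)]
    runs = []
    L = len(motif)
    for s in hits:
        if runs and s - runs[-1][1] <= max_gap:
            runs[-1][1] = s + L
            runs[-1][2] += 1
        else:
            runs.append([s, s + L, 1])
    return runs


def find_telomere_repeats(
    sequence: str,
    seq_id: str = "seq",
    motif: str = "TTTAGGG",
    min_repeats: int = 10,
    max_gap: int = 100,
    terminal_window: int = 10_000,
) -> list[TelomereRegion]:
    """Scan one sequence for tandem telomere-motif arrays on both strands.

    The plant telomere repeat TTTAGGG is the default. A region is
    reported when at least ``min_repeats`` motif copies occur with
    inter-copy gaps of at most ``max_gap`` bp; the ``terminal`` flag marks
    regions whose boundary lies within ``terminal_window`` of either
    sequence end (candidate telomere-to-telomere evidence).
    """
    if not motif or set(motif) - set("ACGT"):
        raise ValueError("motif must be non-empty over ACGT")
    seq = sequence.upper()
    L = len(seq)
    regions = []
    for strand, m in (("+", motif), ("-", reverse_complement(motif))):
        for start, end, n in _motif_runs(seq, m, max_gap):
            if n >= min_repeats:
                terminal = start < terminal_window or (L - end) < terminal_window
                regions.append(TelomereRegion(seq_id, start, end, strand, n, terminal))
    regions.sort(key=lambda r: (r.start, r.strand))
    return regions
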