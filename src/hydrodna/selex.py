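"""HT-SELEX k-mer enrichment analytics.

SELEX pools are compared between a selected cycle ("signal") and an
earlier cycle ("background", by default the unselected input library,
cycle 0).  For a k-mer the *normalized count* is its occurrence count
divided by the pool's read count, the *fold change* is the ratio of
normalized counts signal/background, and the *relative enrichment* is
the percentage ratio of its fold change to that of a reference k-mer
(TAAACG by default, which therefore scores exactly 100).  A k-mer is a
*local maximum* of the enrichment landscape when its enrichment strictly
exceeds that of every k-mer at Hamming distance 1.  Per-temperature
enrichment series are summarised by the sign of their Spearman
correlation with temperature.

A seed-based position weight matrix implements single-position-wildcard
("multinomial setting 1") counting: base frequencies at seed position j
are accumulated from reads matching the seed with position j relaxed to
N and all other non-N positions exact, on both strands.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import spearmanr

from . import constants

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SelexError(ValueError):
    """Invalid SELEX input or configuration."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPool:
    reads: list[str]
    cycle: int
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.reads:
            if any(c not in "ACGTN" for c in r):
                raise SelexError(f"read contains non-ACGTN character: {r[:30]}...")

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class KmerTable:
    k: int
    counts: Counter
    total_reads: int
    strand_policy: str  # forward_only | both_strands

    def normalized(self, kmer: str) -> float:
        return self.counts.get(kmer, 0) / self.total_reads


@dataclass
class KmerEnrichment:
    kmer: str
    normalized_count_signal: float
    normalized_count_background: float
    fold_change: float          # may be inf when background count is 0
    enrichment_pct: float | None = None
    is_local_maximum: bool = False


@dataclass
class EnrichmentReport:
    k: int
    entries: dict[str, KmerEnrichment]
    reference_kmer: str
    pseudocount: float
    condition: dict = field(default_factory=dict)

    def enrichment(self, kmer: str) -> float:
        e = self.entries.get(kmer)
        return e.enrichment_pct if e and e.enrichment_pct is not None else 0.0

    def local_maxima(self, collapse_reverse_complements: bool = False) -> list[str]:
        """Flagged k-mers; with both-strand counting every k-mer and its
        reverse complement share a count, so ``collapse_reverse_complements``
        keeps one canonical member per pair (the lexicographic minimum)."""
        maxima = (k for k, e in self.entries.items() if e.is_local_maximum)
        if collapse_reverse_complements:
            return sorted({min(k, reverse_complement(k)) for k in maxima})
        return sorted(maxima)


@dataclass
class PWM:
    seed: str
    counts: np.ndarray        # (len(seed), 4) base counts, columns ACGT
    frequencies: np.ndarray   # column-normalized
    uniform_columns: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTQ / plain-text I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str, cycle: int = 0, condition: dict | None = None) -> ReadPool:
    reads = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]
    return ReadPool(reads, cycle=cycle, condition=condition or {})


def write_fastq(pool: ReadPool, path: str) -> None:
    records = [
        SeqRecord(Seq(r), id=f"read{i}", description="",
                  letter_annotations={"phred_quality": [40] * len(r)})
        for i, r in enumerate(pool.reads)
    ]
    SeqIO.write(records, str(path), "fastq")


def read_plain(path: str, cycle: int = 0, condition: dict | None = None) -> ReadPool:
    with open(path) as fh:
        reads = [line.strip().upper() for line in fh if line.strip()]
    return ReadPool(reads, cycle=cycle, condition=condition or {})


# ---------------------------------------------------------------------------
# counting and enrichment
# ---------------------------------------------------------------------------

def count_kmers(pool: ReadPool, k: int,
                strand_policy: str = "both_strands") -> KmerTable:
    """Count every overlapping k-mer occurrence across all reads.

    ``both_strands`` additionally scans each read's reverse complement.
    k-mers containing N are never counted.
    """
    if strand_policy not in ("forward_only", "both_strands"):
        raise SelexError(f"unknown strand policy {strand_policy!r}")
    if pool.reads and k > max(len(r) for r in pool.reads):
        raise SelexError(f"k={k} exceeds longest read")
    counts: Counter = Counter()
    for read in pool.reads:
        seqs = (read,) if strand_policy == "forward_only" else (
            read, reverse_complement(read))
        for s in seqs:
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                if "N" not in km:
                    counts[km] += 1
    return KmerTable(k=k, counts=counts, total_reads=pool.n_reads,
                     strand_policy=strand_policy)


def fold_change(signal: KmerTable, background: KmerTable, kmer: str,
                pseudocount: float = 0.0) -> float:
    """(count_sig/reads_sig) / (count_bg/reads_bg), optionally with a
    pseudocount added to both raw counts.  A zero background without a
    pseudocount yields inf (flagged downstream)."""
    if signal.k != background.k:
        raise SelexError("signal and background tables use different k")
    cs = signal.counts.get(kmer, 0) + pseudocount
    cb = background.counts.get(kmer, 0) + pseudocount
    ns = cs / signal.total_reads
    nb = cb / background.total_reads
    if nb == 0:
        return math.inf if ns > 0 else 0.0
    return ns / nb


def compute_enrichment(
    signal: KmerTable,
    background: KmerTable,
    reference_kmer: str = constants.REFERENCE_KMER,
    pseudocount: float = 0.0,
    condition: dict | None = None,
    min_fold_change: float = 2.0,
    include_shifts: bool = True,
) -> EnrichmentReport:
    """Fold changes and relative enrichment for every observed k-mer,
    with local-maxima flags over the related-sequence neighborhood
    (see :func:`flag_local_maxima`)."""
    if len(reference_kmer) != signal.k:
        raise SelexError(
            f"reference k-mer {reference_kmer!r} has length "
            f"{len(reference_kmer)}, tables use k={signal.k}"
        )
    if signal.counts.get(reference_kmer, 0) == 0 and pseudocount == 0:
        raise SelexError(
            f"reference k-mer {reference_kmer!r} absent from signal pool"
        )
    kmers = set(signal.counts) | set(background.counts)
    entries: dict[str, KmerEnrichment] = {}
    for km in kmers:
        fc = fold_change(signal, background, km, pseudocount)
        entries[km] = KmerEnrichment(
            kmer=km,
            normalized_count_signal=signal.normalized(km),
            normalized_count_background=background.normalized(km),
            fold_change=fc,
        )
    ref_fc = entries[reference_kmer].fold_change
    if not math.isfinite(ref_fc) or ref_fc <= 0:
        raise SelexError(f"reference fold change is {ref_fc}; cannot normalise")
    for e in entries.values():
        e.enrichment_pct = (100.0 * e.fold_change / ref_fc
                            if math.isfinite(e.fold_change) else None)
    report = EnrichmentReport(k=signal.k, entries=entries,
                              reference_kmer=reference_kmer,
                              pseudocount=pseudocount,
                              condition=condition or {})
    flag_local_maxima(report, min_fold_change=min_fold_change,
                      include_shifts=include_shifts)
    return report


def hamming1_neighbors(kmer: str) -> list[str]:
    out = []
    for i, c in enumerate(kmer):
        for b in ALPHABET:
            if b != c:
                out.append(kmer[:i] + b + kmer[i + 1:])
    return out


def shift_neighbors(kmer: str) -> list[str]:
    """Same-length k-mers overlapping ``kmer`` by k-1 (single-base shifts
    in either direction, any incoming base)."""
    out = []
    for b in ALPHABET:
        out.append(kmer[1:] + b)
        out.append(b + kmer[:-1])
    return [s for s in out if s != kmer]


def related_sequences(kmer: str, include_shifts: bool = True) -> list[str]:
    rel = hamming1_neighbors(kmer)
    if include_shifts:
        rel += shift_neighbors(kmer)
    return rel


def flag_local_maxima(report: EnrichmentReport,
                      min_fold_change: float = 2.0,
                      include_shifts: bool = True) -> None:
    """A k-mer is a local maximum iff its enrichment strictly exceeds the
    enrichment of every related sequence (absent relatives score 0).

    Related sequences are the Hamming-1 neighbors and, by default, the
    single-base shifts - a k-mer overlapping an optimum by k-1 bases
    rides the optimum's enrichment with a flat substitution
    neighborhood, and only the shift comparison removes it.  Candidates
    must change at least ``min_fold_change``-fold over background, which
    suppresses spurious maxima in the sampling noise of unenriched
    k-mers; k-mers with non-finite fold change are excluded.
    """
    for km, e in report.entries.items():
        if e.enrichment_pct is None or e.fold_change < min_fold_change:
            e.is_local_maximum = False
            continue
        e.is_local_maximum = all(
            e.enrichment_pct > report.enrichment(nb)
            for nb in related_sequences(km, include_shifts)
        )


def relative_enrichment(report: EnrichmentReport, kmer: str) -> float:
    e = report.entries.get(kmer)
    if e is None or e.enrichment_pct is None:
        raise SelexError(f"no finite enrichment for {kmer!r}")
    return e.enrichment_pct


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------

@dataclass
class TemperatureTrend:
    kmer: str
    temperatures: list[float]
    enrichment_pct: list[float]
    spearman: float
    trend_sign: int   # -1 decreasing, 0 flat/undetermined, +1 increasing


def temperature_profile(
    reports: Mapping[float, EnrichmentReport],
    kmers: Sequence[str] | None = None,
    measure: str = "enrichment_pct",
) -> list[TemperatureTrend]:
    """Per-k-mer enrichment across a temperature series (Celsius keys)
    with a monotone-trend summary (sign of the Spearman correlation).

    ``measure`` selects the profiled quantity: ``enrichment_pct``
    (relative to the reference k-mer, which is therefore flat by
    construction) or ``fold_change`` (absolute against background; use
    this when the reference itself responds to temperature).
    """
    if measure not in ("enrichment_pct", "fold_change"):
        raise SelexError(f"unknown measure {measure!r}")
    if not reports:
        raise SelexError("temperature_profile needs at least one report")
    temps = sorted(reports)
    first = reports[temps[0]]
    for t in temps:
        if reports[t].k != first.k or reports[t].reference_kmer != first.reference_kmer:
            raise SelexError("reports must share k and reference k-mer")
    if kmers is None:
        kmers = sorted(set().union(*(set(reports[t].entries) for t in temps)))

    def value(report: EnrichmentReport, km: str) -> float:
        if measure == "enrichment_pct":
            return report.enrichment(km)
        e = report.entries.get(km)
        return e.fold_change if e and math.isfinite(e.fold_change) else 0.0

    out = []
    for km in kmers:
        values = [value(reports[t], km) for t in temps]
        spread = max(values) - min(values)
        scale = max(1.0, max(abs(v) for v in values))
        if spread <= 1e-9 * scale or len(temps) < 2:
            rho, sign = 0.0, 0  # flat to numerical precision
        else:
            rho = float(spearmanr(temps, values).statistic)
            if math.isnan(rho):
                rho, sign = 0.0, 0
            else:
                sign = int(np.sign(rho))
        out.append(TemperatureTrend(kmer=km, temperatures=list(temps),
                                    enrichment_pct=values, spearman=rho,
                                    trend_sign=sign))
    return out


# ---------------------------------------------------------------------------
# seed PWM
# ---------------------------------------------------------------------------

def seed_pwm(pool: ReadPool, seed: str,
             strand_policy: str = "both_strands") -> PWM:
    """Single-position-wildcard seed PWM.

    For each seed position j, every window (either strand) matching the
    seed with position j relaxed contributes its base at j to column j.
    Equivalently: a window matching the seed exactly at all non-N
    positions contributes to every column; a window with exactly one
    mismatch contributes only to the mismatched column.  Columns with no
    matching windows are set uniform and flagged.
    """
    seed = seed.upper()
    if any(c not in "ACGTN" for c in seed):
        raise SelexError(f"seed must be over ACGTN: {seed!r}")
    L = len(seed)
    if not pool.reads or L > max(len(r) for r in pool.reads):
        raise SelexError("seed longer than the reads")
    counts = np.zeros((L, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    fixed = [j for j in range(L) if seed[j] != "N"]
    for read in pool.reads:
        seqs = (read,) if strand_policy == "forward_only" else (
            read, reverse_complement(read))
        for s in seqs:
            for i in range(len(s) - L + 1):
                window = s[i:i + L]
                if "N" in window:
                    continue
                mismatches = [j for j in fixed if window[j] != seed[j]]
                if len(mismatches) == 0:
                    for j in range(L):
                        counts[j, base_idx[window[j]]] += 1
                elif len(mismatches) == 1:
                    j = mismatches[0]
                    counts[j, base_idx[window[j]]] += 1
    freqs = np.zeros_like(counts)
    uniform = []
    for j in range(L):
        total = counts[j].sum()
        if total == 0:
            freqs[j] = 0.25
            uniform.append(j)
        else:
            freqs[j] = counts[j] / total
    return PWM(seed=seed, counts=counts, frequencies=freqs,
               uniform_columns=uniform)


def report_to_rows(report: EnrichmentReport) -> list[dict]:
    rows = []
    for km in sorted(report.entries):
        e = report.entries[km]
        rows.append({
            "kmer": km,
            "normalized_count_signal": e.normalized_count_signal,
            "normalized_count_background": e.normalized_count_background,
            "fold_change": e.fold_change,
            "enrichment_pct": e.enrichment_pct,
            "is_local_max": e.is_local_maximum,
        })
    return rows
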