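"""Intra-individual (heteroplasmic) variant calling from read pileups.

Parses the samtools text-pileup dialect, calls sub-consensus variants with
VarScan-style thresholds (minimum supporting reads, minimum variant
frequency, consensus cutoff), assigns a one-sided binomial p-value against a
flat sequencing-error rate, and summarises calls per gene into frequency
bins, indel composition reports, invariable-region scans and per-gene
frequency-occupancy patterns.

Indels are represented as anchored ref/alt strings (``CA -> C`` for a
deletion of A after the anchor C; ``C -> CA`` for the matching insertion),
positioned at the anchor base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .genome_model import GeneAnnotation
from .polymorphism import FreqBinTable, TRANSITION_PAIRS

logger = logging.getLogger(__name__)

SUB_TRANSITION = "substitution-transition"
SUB_TRANSVERSION = "substitution-transversion"
INSERTION = "insertion"
DELETION = "deletion"

PROGRESSIVE = "progressive"
GAPPED = "gapped"
LONE_HIGH = "lone_high"


class PileupParseError(ValueError):
    """Malformed pileup line (reported with its line number)."""


@dataclass
class PileupSite:
    """Per-position tally of read base calls.

    ``base_calls`` keys are A/C/G/T/N, ``*`` (within-deletion placeholder),
    ``+SEQ`` for insertions after this position and ``-SEQ`` for deletions of
    SEQ starting after this position.  Insertion/deletion events ride on a
    base call, so substitution + reference counts never exceed coverage.
    """

    position: int
    ref_base: str
    coverage: int
    base_calls: dict[str, int] = field(default_factory=dict)

    def support(self, call: str) -> int:
        return self.base_calls.get(call, 0)


@dataclass(frozen=True)
class HetCallerParams:
    """VarScan-style calling thresholds plus the error model.

    ``error_rate`` is the flat per-base sequencing-error probability of the
    binomial null; calls with p >= ``alpha`` are retained but flagged
    not-called and excluded from summaries.
    """

    min_var_reads: int = 4
    min_freq_for_hom: float = 0.5
    min_var_freq: float = 0.0
    error_rate: float = 0.01
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_var_reads < 1:
            raise ValueError("min_var_reads must be >= 1")
        for name in ("min_freq_for_hom", "min_var_freq", "error_rate", "alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class HetVariant:
    """One heteroplasmic call with anchored ref/alt representation."""

    position: int
    ref_allele: str
    alt_allele: str
    var_type: str
    supporting_reads: int
    coverage: int
    frequency: float
    p_value: float
    zygosity_call: str
    called: bool = True
    homopolymer_run: int | None = None

    @property
    def indel_seq(self) -> str | None:
        if self.var_type == INSERTION:
            return self.alt_allele[len(self.ref_allele):]
        if self.var_type == DELETION:
            return self.ref_allele[len(self.alt_allele):]
        return None


# ---------------------------------------------------------------------------
# Pileup I/O


def _parse_bases(bases: str, ref: str, lineno: int) -> dict[str, int]:
    calls: dict[str, int] = {}
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # mapping-quality char follows
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"line {lineno}: indel without length at offset {i}")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length].upper()
            if len(seq) != length:
                raise PileupParseError(f"line {lineno}: truncated indel sequence")
            key = f"{c}{seq}"
            calls[key] = calls.get(key, 0) + 1
            i = j + length
            continue
        if c in ".,":
            calls[ref] = calls.get(ref, 0) + 1
        elif c.upper() in "ACGTN":
            key = c.upper()
            calls[key] = calls.get(key, 0) + 1
        elif c == "*":
            calls["*"] = calls.get("*", 0) + 1
        else:
            raise PileupParseError(f"line {lineno}: unexpected pileup symbol {c!r}")
        i += 1
    return calls


def read_pileup(path: str | Path) -> list[PileupSite]:
    """Read a samtools-style 6-column text pileup."""
    sites: list[PileupSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PileupParseError(f"line {lineno}: expected >= 5 columns")
            try:
                pos, ref, cov = int(fields[1]), fields[2].upper(), int(fields[3])
            except ValueError as exc:
                raise PileupParseError(f"line {lineno}: {exc}") from exc
            calls = _parse_bases(fields[4], ref, lineno)
            sites.append(PileupSite(position=pos, ref_base=ref, coverage=cov, base_calls=calls))
    return sites


def write_pileup(sites: list[PileupSite], path: str | Path, chrom: str = "chrM") -> None:
    """Write sites back to the samtools text dialect (ref matches as '.')."""
    with open(path, "w") as fh:
        for s in sites:
            parts: list[str] = []
            n_base_calls = 0
            for call, count in sorted(s.base_calls.items()):
                if call.startswith(("+", "-")):
                    sym = f"{call[0]}{len(call) - 1}{call[1:]}"
                    parts.append(sym * count)
                else:
                    sym = "." if call == s.ref_base else call
                    parts.append(sym * count)
                    n_base_calls += count
            quals = "I" * n_base_calls
            fh.write(f"{chrom}\t{s.position}\t{s.ref_base}\t{s.coverage}\t"
                     f"{''.join(parts)}\t{quals}\n")


# ---------------------------------------------------------------------------
# Calling


def _variant_from_call(
    site: PileupSite, call: str, support: int, params: HetCallerParams
) -> HetVariant:
    freq = support / site.coverage
    p = float(stats.binom.sf(support - 1, site.coverage, params.error_rate))
    if call.startswith("+"):
        var_type, ref, alt = INSERTION, site.ref_base, site.ref_base + call[1:]
    elif call.startswith("-"):
        var_type, ref, alt = DELETION, site.ref_base + call[1:], site.ref_base
    else:
        pair = frozenset((site.ref_base, call))
        var_type = SUB_TRANSITION if pair in TRANSITION_PAIRS else SUB_TRANSVERSION
        ref, alt = site.ref_base, call
    return HetVariant(
        position=site.position,
        ref_allele=ref,
        alt_allele=alt,
        var_type=var_type,
        supporting_reads=support,
        coverage=site.coverage,
        frequency=freq,
        p_value=p,
        zygosity_call="consensus" if freq >= params.min_freq_for_hom else "heteroplasmic",
        called=p < params.alpha,
    )


def call_variants(
    sites: list[PileupSite],
    params: HetCallerParams = HetCallerParams(),
    genome_sequence: str | None = None,
) -> list[HetVariant]:
    """Call every non-reference pileup observation passing the thresholds.

    Zero-coverage sites are skipped.  Calls failing the binomial error test
    keep ``called=False`` and are excluded from downstream summaries.  When
    the genome sequence is given, each indel is annotated with the length of
    the homopolymer run of its indel base around the anchor (context for
    downstream filtering; never used to filter here).
    """
    variants: list[HetVariant] = []
    for site in sites:
        if site.coverage <= 0:
            continue
        for call, support in sorted(site.base_calls.items()):
            if call in (site.ref_base, "*", "N"):
                continue
            if support < params.min_var_reads:
                continue
            if support / site.coverage < params.min_var_freq:
                continue
            v = _variant_from_call(site, call, support, params)
            if genome_sequence is not None and v.indel_seq:
                v.homopolymer_run = _homopolymer_run(
                    genome_sequence, site.position, v.indel_seq[0]
                )
            variants.append(v)
    logger.info(
        "called %d variants (%d pass the error test)",
        len(variants), sum(v.called for v in variants),
    )
    return variants


def _homopolymer_run(seq: str, position: int, base: str) -> int:
    """Longest run of ``base`` adjacent to the 1-based anchor position."""
    i = position  # 0-based index of the base after the anchor
    run = 0
    j = i
    while j < len(seq) and seq[j] == base:
        run += 1
        j += 1
    j = i - 1
    while j >= 0 and seq[j] == base:
        run += 1
        j -= 1
    return run


# ---------------------------------------------------------------------------
# Summaries


def summarize_by_gene(
    variants: list[HetVariant],
    annotations: list[GeneAnnotation],
    L: int | None = None,
    bin_width: float = 10.0,
    n_bins: int = 6,
) -> FreqBinTable:
    """Per-gene counts over (0,10] .. (50,60] frequency bins, VI-sorted.

    Only called variants inside annotated genes contribute; intergenic
    positions are excluded (the reported universe covers genes and CR
    segments only).
    """
    lengths = {a.gene_name: float(a.length(L)) for a in annotations}
    groups = {a.gene_name: a.gene_group for a in annotations}
    table = FreqBinTable.with_width(
        bin_width=bin_width, max_pct=bin_width * n_bins, lengths=lengths, groups=groups
    )
    for v in variants:
        if not v.called:
            continue
        genes = [a.gene_name for a in annotations if a.contains(v.position, L)]
        for g in genes:
            table.add(g, 100.0 * v.frequency)
            table.count_site(g)
    return table


def gene_table_frame(table: FreqBinTable) -> pd.DataFrame:
    """Table-5-style frame: one row per gene with variants, VI-descending,
    plus the frequency-occupancy pattern label."""
    df = table.to_frame(sort_by_vi=True, decimals=0)
    if df.empty:
        return df
    patterns = []
    for name in df["name"]:
        patterns.append(frequency_gap_pattern(table.rows[name]))
    df["pattern"] = patterns
    return df


def indel_composition(variants: list[HetVariant]) -> dict:
    """Composition of called indels by type, sequence, base and length.

    Reports per-sequence counts for insertions and deletions, the share of
    deletions involving each base (an indel "involves" every base its
    sequence contains), the largest indel length, and totals.
    """
    ins: dict[str, int] = {}
    dels: dict[str, int] = {}
    n_sub = 0
    for v in variants:
        if not v.called:
            continue
        seq = v.indel_seq
        if v.var_type == INSERTION:
            ins[seq] = ins.get(seq, 0) + 1
        elif v.var_type == DELETION:
            dels[seq] = dels.get(seq, 0) + 1
        else:
            n_sub += 1
    n_ins, n_del = sum(ins.values()), sum(dels.values())

    def base_involvement(counter: dict[str, int]) -> dict[str, int]:
        out = {b: 0 for b in "ACGT"}
        for seq, c in counter.items():
            for b in set(seq):
                out[b] += c
        return out

    del_bases = base_involvement(dels)
    deletion_base_share_pct = {
        b: (100.0 * c / n_del if n_del else 0.0) for b, c in del_bases.items()
    }
    all_lengths = [len(s) for s in list(ins) + list(dels)]
    return {
        "n_insertions": n_ins,
        "n_deletions": n_del,
        "n_substitutions": n_sub,
        "insertions_by_seq": dict(sorted(ins.items(), key=lambda kv: -kv[1])),
        "deletions_by_seq": dict(sorted(dels.items(), key=lambda kv: -kv[1])),
        "insertion_base_counts": base_involvement(ins),
        "deletion_base_counts": del_bases,
        "deletion_base_share_pct": deletion_base_share_pct,
        "largest_indel_bp": max(all_lengths, default=0),
    }


def invariable_regions(
    positions: list[int], L: int, circular: bool = True, floor: int = 0
) -> list[dict]:
    """Gaps between consecutive variant positions, largest first.

    Gap length is the positional difference between neighbours (wrap-around
    included when circular); a single variant on a circular genome yields one
    gap of length L.  Only gaps >= ``floor`` are returned.
    """
    pos = sorted(set(positions))
    if not pos:
        raise ValueError("need at least one variant position")
    gaps: list[dict] = []
    for a, b in zip(pos, pos[1:]):
        gaps.append({"from_pos": a, "to_pos": b, "gap_bp": b - a})
    if circular:
        wrap = L - pos[-1] + pos[0] if len(pos) > 1 else L
        gaps.append({"from_pos": pos[-1], "to_pos": pos[0], "gap_bp": wrap})
    gaps = [g for g in gaps if g["gap_bp"] >= floor]
    return sorted(gaps, key=lambda g: -g["gap_bp"])


def frequency_gap_pattern(bin_counts: np.ndarray) -> str:
    """Classify a gene's frequency-bin occupancy.

    ``progressive`` when the occupied bins form a prefix starting at (0,10]
    (variants fill an interval before occupying the next), ``lone_high`` when
    exactly one bin is occupied and it is not the lowest, ``gapped``
    otherwise (occupancy with holes, the l-rRNA shape).
    """
    occupied = np.flatnonzero(np.asarray(bin_counts) > 0)
    if occupied.size == 0:
        raise ValueError("row has no occupied bins")
    if occupied[0] == 0 and occupied[-1] == occupied.size - 1:
        return PROGRESSIVE
    if occupied.size == 1:
        return LONE_HIGH
    return GAPPED


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    variants: list[HetVariant], path: str | Path, chrom: str = "chrM",
    contig_length: int | None = None, header_extra: list[str] | None = None,
) -> None:
    lines = ["##fileformat=VCFv4.2"]
    if contig_length:
        lines.append(f"##contig=<ID={chrom},length={contig_length}>")
    lines += header_extra or []
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read coverage">',
        '##INFO=<ID=AD,Number=1,Type=Integer,Description="Reads supporting the variant">',
        '##INFO=<ID=FREQ,Number=1,Type=Float,Description="Variant allele frequency">',
        '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in sorted(variants, key=lambda x: x.position):
        filt = "PASS" if v.called else "not_called"
        info = (
            f"DP={v.coverage};AD={v.supporting_reads};"
            f"FREQ={v.frequency:.4f};VT={v.var_type}"
        )
        lines.append(
            f"{chrom}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t{filt}\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_variants(path: str | Path) -> list[HetVariant]:
    """Read calls back from a VCF written by :func:`write_vcf` (or any plain
    VCF carrying DP/AD/FREQ info fields)."""
    variants: list[HetVariant] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _, ref, alt, _, filt, info = line.split("\t")[:8]
        kv = dict(p.split("=", 1) for p in info.split(";") if "=" in p)
        dp = int(kv.get("DP", 0))
        ad = int(kv.get("AD", 0))
        freq = float(kv.get("FREQ", ad / dp if dp else 0.0))
        if len(ref) > len(alt):
            vt = DELETION
        elif len(alt) > len(ref):
            vt = INSERTION
        else:
            pair = frozenset((ref, alt))
            vt = SUB_TRANSITION if pair in TRANSITION_PAIRS else SUB_TRANSVERSION
        variants.append(
            HetVariant(
                position=int(pos), ref_allele=ref, alt_allele=alt, var_type=vt,
                supporting_reads=ad, coverage=dp, frequency=freq, p_value=0.0,
                zygosity_call="heteroplasmic" if freq < 0.5 else "consensus",
                called=filt in ("PASS", "."),
            )
        )
    return variants


class HeteroplasmyCaller(BaseEstimator):
    """VarScan-style heteroplasmy caller over a parsed pileup.

    Parameters follow :class:`HetCallerParams`; fit() consumes a list of
    :class:`PileupSite` and exposes ``variants_`` (all calls) and
    ``called_variants_`` (those passing the binomial error test).
    """

    def __init__(
        self,
        min_var_reads: int = 4,
        min_freq_for_hom: float = 0.5,
        min_var_freq: float = 0.0,
        error_rate: float = 0.01,
        alpha: float = 0.05,
    ):
        self.min_var_reads = min_var_reads
        self.min_freq_for_hom = min_freq_for_hom
        self.min_var_freq = min_var_freq
        self.error_rate = error_rate
        self.alpha = alpha

    def _params(self) -> HetCallerParams:
        return HetCallerParams(
            min_var_reads=self.min_var_reads,
            min_freq_for_hom=self.min_freq_for_hom,
            min_var_freq=self.min_var_freq,
            error_rate=self.error_rate,
            alpha=self.alpha,
        )

    def fit(self, pileup: list[PileupSite], y=None,
            genome_sequence: str | None = None) -> "HeteroplasmyCaller":
        self.variants_ = call_variants(pileup, self._params(), genome_sequence)
        self.called_variants_ = [v for v in self.variants_ if v.called]
        return self

    def gene_table(self, annotations: list[GeneAnnotation],
                   L: int | None = None, n_bins: int = 6) -> FreqBinTable:
        self._check_fitted()
        return summarize_by_gene(self.called_variants_, annotations, L=L, n_bins=n_bins)

    def composition(self) -> dict:
        self._check_fitted()
        return indel_composition(self.called_variants_)

    def invariable_regions(self, L: int, circular: bool = True, floor: int = 0) -> list[dict]:
        self._check_fitted()
        return invariable_regions(
            [v.position for v in self.called_variants_], L, circular=circular, floor=floor
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "variants_"):
            raise RuntimeError("caller is not fitted; call fit(pileup) first")
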