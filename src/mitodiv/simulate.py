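"""Synthetic data with the statistical structure of shrimp mitogenome panels.

Three generators, each with serialized ground truth so every downstream stage
can be tested without external downloads:

* :func:`generate_cr_panel` — an aligned control-region haplotype panel
  (default: 45 haplotypes, seven conserved segments interleaved with seven
  variable segments whose lengths and planted polymorphic-column counts are
  the reported study values).  Allele frequencies are planted as exact counts
  — census ratios, not samples.
* :func:`generate_genome_quartet` — four complete mitogenomes mutated from a
  common ancestor with planted singleton (25%) and doubleton (50%) variants
  per gene; the default per-gene plan is the reported inter-individual table.
* :func:`generate_het_pileup` — a single-genome read pileup with planted
  heteroplasmic variants (mostly single-base A/T indels at sub-50%
  frequencies); read support is drawn binomially at the planted fraction and
  coverage from a negative binomial matched to the reported mean 128.4 /
  SD 51.3, with an exact-counts "noise off" mode for identity tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_model import CircularGenome, GeneAnnotation, Msa
from .heteroplasmy import PileupSite

# ---------------------------------------------------------------------------
# Control-region panel

# Segment plan shaped like the characterised control region: CS lengths,
# VS lengths and per-VS polymorphic-column counts, 5'->3'.
DEFAULT_CS_LENGTHS = (40, 27, 23, 20, 27, 35, 24)
DEFAULT_VS_LENGTHS = (55, 89, 354, 110, 11, 130, 56)
DEFAULT_VS_VARIANTS = (7, 19, 95, 18, 3, 26, 14)

# Pool of planted carrier counts (out of n haplotypes); drawn uniformly, so
# most variants are low-frequency, as in the observed spectrum.
DEFAULT_CARRIER_POOL = (1, 1, 1, 2, 2, 3, 4, 4, 5, 7, 9, 12, 15, 18, 20, 22)

# Site-type mix (transition / transversion / both / indel / indel+transition),
# matching the observed shares of the 182 control-region sites.
DEFAULT_TYPE_WEIGHTS = {
    "ti": 0.786,
    "tv": 0.088,
    "ti+tv": 0.060,
    "indel": 0.050,
    "indel+ti": 0.016,
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# AT-rich base composition typical of the control region (~12% GC).
CR_BASE_P = {"A": 0.38, "C": 0.07, "G": 0.05, "T": 0.50}
# Whole-mitogenome composition (~32% GC).
MT_BASE_P = {"A": 0.34, "C": 0.16, "G": 0.16, "T": 0.34}


@dataclass(frozen=True)
class PanelConfig:
    """Layout and variant plan for the synthetic control-region panel."""

    n_haplotypes: int = 45
    cs_lengths: tuple[int, ...] = DEFAULT_CS_LENGTHS
    vs_lengths: tuple[int, ...] = DEFAULT_VS_LENGTHS
    vs_variant_counts: tuple[int, ...] = DEFAULT_VS_VARIANTS
    carrier_pool: tuple[int, ...] = DEFAULT_CARRIER_POOL
    type_weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_TYPE_WEIGHTS.items())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if len(self.vs_lengths) != len(self.vs_variant_counts):
            raise ValueError("vs_lengths and vs_variant_counts must align")
        for ln, nv in zip(self.vs_lengths, self.vs_variant_counts):
            if nv > ln:
                raise ValueError("more planted variants than columns in a VS")
        if max(self.carrier_pool) > (self.n_haplotypes - 1) // 2:
            raise ValueError("carrier counts must keep variants below 50% frequency")


@dataclass
class PlantedSite:
    """Ground truth for one planted polymorphic column."""

    column: int  # 1-based alignment column == reference position
    segment: str
    ancestral: str
    alt_alleles: tuple[str, ...]
    carrier_counts: tuple[int, ...]
    site_type: str


@dataclass
class PanelTruth:
    """Serialized ground truth of a generated control-region panel."""

    n_haplotypes: int
    segments: list[dict]  # label, kind, start, end (alignment columns)
    variants: list[PlantedSite]
    vs_variant_counts: dict[str, int]

    @property
    def n_polymorphic(self) -> int:
        return len(self.variants)

    def frequencies(self) -> dict[int, tuple[float, ...]]:
        n = self.n_haplotypes
        return {v.column: tuple(c / n for c in v.carrier_counts) for v in self.variants}

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_haplotypes": self.n_haplotypes,
                "segments": self.segments,
                "vs_variant_counts": self.vs_variant_counts,
                "variants": [dataclasses.asdict(v) for v in self.variants],
            },
            indent=1,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _draw_sequence(rng: np.random.Generator, length: int, base_p: dict[str, float]) -> np.ndarray:
    bases = np.array(list(base_p))
    p = np.array(list(base_p.values()))
    return rng.choice(bases, size=length, p=p / p.sum())


def _variant_offsets(length: int, n: int) -> np.ndarray:
    """Evenly spaced 0-based offsets including both block edges, so recovered
    segment boundaries coincide with the planted ones."""
    if n == 1:
        return np.array([0])
    off = np.unique(np.round(np.linspace(0, length - 1, n)).astype(int))
    if off.size != n:  # rounding collision; fall back to the first n offsets
        off = np.arange(n)
    return off


def generate_cr_panel(config: PanelConfig = PanelConfig()) -> tuple[Msa, PanelTruth]:
    """Aligned haplotype panel with planted conserved runs and variants.

    Conserved-segment columns are identical across all haplotypes; each
    planted variant column realises its alternate allele(s) in an exact
    number of carrier haplotypes (never the coordinate-reference haplotype
    for indels, so reference positions equal alignment columns).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_haplotypes
    labels: list[tuple[str, str, int]] = []  # (label, kind, length)
    for i in range(max(len(config.cs_lengths), len(config.vs_lengths))):
        if i < len(config.cs_lengths):
            labels.append((f"CS{i + 1}", "conserved", config.cs_lengths[i]))
        if i < len(config.vs_lengths):
            labels.append((f"VS{i + 1}", "variable", config.vs_lengths[i]))
    total = sum(ln for _, _, ln in labels)
    ancestral = _draw_sequence(rng, total, CR_BASE_P)
    matrix = np.tile(ancestral, (n, 1))

    type_names = [t for t, _ in config.type_weights]
    type_p = np.array([w for _, w in config.type_weights])
    type_p = type_p / type_p.sum()

    segments: list[dict] = []
    variants: list[PlantedSite] = []
    vs_counts: dict[str, int] = {}
    cursor = 0
    vi = 0
    for label, kind, length in labels:
        start, end = cursor + 1, cursor + length
        segments.append({"label": label, "kind": kind, "start": start, "end": end})
        if kind == "variable":
            n_var = config.vs_variant_counts[vi]
            vi += 1
            vs_counts[label] = n_var
            for off in _variant_offsets(length, n_var):
                col = cursor + int(off)  # 0-based
                anc = str(ancestral[col])
                stype = str(rng.choice(type_names, p=type_p))
                k = int(rng.choice(config.carrier_pool))
                alts: list[str]
                counts: list[int]
                if stype in ("ti+tv", "indel+ti"):
                    k = max(k, 2)
                    second = _TRANSITION[anc]
                    first = "-" if stype == "indel+ti" else str(
                        rng.choice(list(_TRANSVERSIONS[anc]))
                    )
                    alts = [first, second]
                    counts = [k - k // 2, k // 2]
                elif stype == "tv":
                    alts = [str(rng.choice(list(_TRANSVERSIONS[anc])))]
                    counts = [k]
                elif stype == "indel":
                    alts = ["-"]
                    counts = [k]
                else:  # transition
                    alts = [_TRANSITION[anc]]
                    counts = [k]
                carriers = rng.choice(np.arange(1, n), size=sum(counts), replace=False)
                pos = 0
                for alt, c in zip(alts, counts):
                    matrix[carriers[pos : pos + c], col] = alt
                    pos += c
                variants.append(
                    PlantedSite(
                        column=col + 1,
                        segment=label,
                        ancestral=anc,
                        alt_alleles=tuple(alts),
                        carrier_counts=tuple(counts),
                        site_type=stype,
                    )
                )
        cursor += length

    records = [(f"hap{i + 1:02d}", "".join(row)) for i, row in enumerate(matrix)]
    msa = Msa(records, reference_id=records[0][0])
    truth = PanelTruth(
        n_haplotypes=n, segments=segments, variants=variants, vs_variant_counts=vs_counts
    )
    return msa, truth


# ---------------------------------------------------------------------------
# Mitogenome quartet

# Per-gene plan of the inter-individual analysis: (name, group, n_singleton
# [25%], n_doubleton [50%], length bp).
DEFAULT_QUARTET_GENES: tuple[tuple[str, str, int, int, int], ...] = (
    ("VS3", "CR", 18, 17, 352),
    ("VS5", "CR", 0, 1, 11),
    ("VS2", "CR", 6, 1, 87),
    ("VS4", "CR", 0, 7, 109),
    ("COX1", "COX", 92, 0, 1534),
    ("VS6", "CR", 4, 3, 129),
    ("tRNA-Tyr", "tRNA", 3, 0, 66),
    ("VS1", "CR", 2, 0, 55),
    ("tRNA-Glu", "tRNA", 0, 2, 70),
    ("VS7", "CR", 0, 1, 56),
    ("tRNA-Ile", "tRNA", 1, 0, 67),
    ("tRNA-Phe", "tRNA", 1, 0, 67),
    ("tRNA-Trp", "tRNA", 1, 0, 69),
    ("tRNA-Val", "tRNA", 1, 0, 72),
    ("COX2", "COX", 4, 3, 688),
    ("ND1", "ND", 5, 2, 938),
    ("ND2", "ND", 7, 0, 1000),
    ("ND5", "ND", 6, 3, 1723),
    ("CYTB", "COX", 4, 0, 1136),
    ("s-rRNA", "rRNA", 3, 0, 856),
    ("ND4L", "ND", 0, 1, 300),
    ("ND4", "ND", 3, 1, 1341),
    ("ATP6", "ATP", 2, 0, 675),
    ("l-rRNA", "rRNA", 2, 2, 1370),
    ("ND3", "ND", 1, 0, 352),
    ("ND6", "ND", 1, 0, 516),
    ("COX3", "COX", 1, 0, 790),
)


@dataclass(frozen=True)
class QuartetConfig:
    genome_length: int = 15989
    genes: tuple[tuple[str, str, int, int, int], ...] = DEFAULT_QUARTET_GENES
    transition_fraction: float = 0.8
    seed: int = 0


@dataclass
class QuartetTruth:
    per_gene: dict[str, dict]  # name -> {n25, n50, length, positions}
    positions: list[int]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def to_json(self) -> str:
        return json.dumps({"per_gene": self.per_gene, "positions": self.positions}, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def generate_genome_quartet(
    config: QuartetConfig = QuartetConfig(),
) -> tuple[Msa, list[GeneAnnotation], QuartetTruth]:
    """Four equal-length genomes from one ancestor, with per-gene planted
    singleton (1 of 4) and doubleton (2 vs 2) substitution sites.

    The alignment is trivially columnwise (no planted length changes), so the
    coordinate map is the identity.  The coordinate-reference genome carries
    the ancestral allele at every planted site, making the 50/50 tie-break
    resolve to the ancestor.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    total_genes = sum(g[4] for g in config.genes)
    if total_genes > L:
        raise ValueError("gene lengths exceed the genome length")
    spacer = (L - total_genes) // len(config.genes)
    ancestor = _draw_sequence(rng, L, MT_BASE_P)
    matrix = np.tile(ancestor, (4, 1))

    annotations: list[GeneAnnotation] = []
    per_gene: dict[str, dict] = {}
    all_positions: list[int] = []
    singleton_cycle = (1, 2, 3)
    doubleton_cycle = ((1, 2), (1, 3), (2, 3))
    ci = di = 0
    cursor = 0
    for name, group, n25, n50, length in config.genes:
        start = cursor + 1
        end = cursor + length
        annotations.append(GeneAnnotation(name, group, ((start, end),)))
        pos = rng.choice(np.arange(start, end + 1), size=n25 + n50, replace=False)
        pos.sort()
        gene_positions = []
        for m, p in enumerate(pos):
            anc = str(ancestor[p - 1])
            if rng.random() < config.transition_fraction:
                alt = _TRANSITION[anc]
            else:
                alt = str(rng.choice(list(_TRANSVERSIONS[anc])))
            if m < n25:
                carriers = (singleton_cycle[ci % 3],)
                ci += 1
                klass = 25
            else:
                carriers = doubleton_cycle[di % 3]
                di += 1
                klass = 50
            for c in carriers:
                matrix[c, p - 1] = alt
            gene_positions.append({"position": int(p), "alt": alt, "class_pct": klass})
            all_positions.append(int(p))
        per_gene[name] = {
            "group": group, "n25": n25, "n50": n50, "length": length,
            "positions": gene_positions,
        }
        cursor = end + spacer
    records = [(f"mito{i + 1}", "".join(row)) for i, row in enumerate(matrix)]
    msa = Msa(records, reference_id="mito1")
    return msa, annotations, QuartetTruth(per_gene=per_gene, positions=sorted(all_positions))


# ---------------------------------------------------------------------------
# Heteroplasmic pileup

# Per-gene plan of the intra-individual analysis: (name, group, length,
# counts over the six 10%-wide frequency bins).
DEFAULT_HET_GENES: tuple[tuple[str, str, int, tuple[int, ...]], ...] = (
    ("ND3", "ND", 352, (5, 7, 1, 0, 0, 0)),
    ("tRNA-Ala", "tRNA", 65, (2, 0, 0, 0, 0, 0)),
    ("tRNA-Arg", "tRNA", 65, (2, 0, 0, 0, 0, 0)),
    ("tRNA-Lys", "tRNA", 69, (1, 1, 0, 0, 0, 0)),
    ("CS6", "CR", 35, (0, 0, 0, 0, 1, 0)),
    ("ND1", "ND", 938, (11, 9, 1, 1, 1, 0)),
    ("ATP8", "ATP", 159, (1, 1, 1, 0, 0, 0)),
    ("VS7", "CR", 56, (0, 0, 1, 0, 0, 0)),
    ("ND6", "ND", 516, (1, 4, 3, 0, 0, 0)),
    ("tRNA-Gly", "tRNA", 66, (0, 1, 0, 0, 0, 0)),
    ("tRNA-Pro", "tRNA", 67, (0, 1, 0, 0, 0, 0)),
    ("tRNA-Thr", "tRNA", 68, (0, 0, 0, 1, 0, 0)),
    ("tRNA-Ser", "tRNA", 68, (0, 1, 0, 0, 0, 0)),
    ("ND5", "ND", 1723, (19, 5, 1, 0, 0, 0)),
    ("tRNA-Asp", "tRNA", 70, (1, 0, 0, 0, 0, 0)),
    ("tRNA-Glu", "tRNA", 70, (1, 0, 0, 0, 0, 0)),
    ("CYTB", "COX", 1136, (12, 3, 1, 0, 0, 0)),
    ("ATP6", "ATP", 675, (8, 1, 0, 0, 0, 0)),
    ("COX1", "COX", 1534, (15, 5, 0, 0, 0, 0)),
    ("COX3", "COX", 790, (5, 3, 2, 0, 0, 0)),
    ("VS2", "CR", 87, (0, 0, 0, 1, 0, 0)),
    ("ND2", "ND", 1000, (6, 4, 1, 0, 0, 0)),
    ("l-rRNA", "rRNA", 1370, (5, 4, 2, 0, 0, 1)),
    ("ND4", "ND", 1341, (5, 4, 1, 0, 0, 0)),
    ("s-rRNA", "rRNA", 856, (3, 2, 0, 0, 0, 0)),
    ("COX2", "COX", 688, (1, 2, 1, 0, 0, 0)),
    ("ND4L", "ND", 300, (0, 0, 1, 0, 0, 0)),
    ("VS3", "CR", 352, (0, 0, 0, 1, 0, 0)),
)

# Indel/substitution composition plan: mostly single-base A/T insertions,
# C/G indels mainly as deletions, three 2-bp events, two transitions.
DEFAULT_COMPOSITION: tuple[tuple[str, str, int], ...] = (
    ("+", "T", 66), ("+", "A", 44), ("+", "AT", 1), ("+", "CT", 1),
    ("-", "T", 36), ("-", "A", 20), ("-", "C", 9), ("-", "G", 6), ("-", "AA", 1),
    ("sub", "", 2),
)


@dataclass(frozen=True)
class HetSimConfig:
    """Depth model, variant plan and noise switches of the pileup generator."""

    genome_length: int = 15989
    genes: tuple[tuple[str, str, int, tuple[int, ...]], ...] = DEFAULT_HET_GENES
    composition: tuple[tuple[str, str, int], ...] = DEFAULT_COMPOSITION
    mean_coverage: float = 128.4
    coverage_sd: float = 51.3
    min_coverage: int = 70
    error_rate: float = 0.0
    exact_counts: bool = False
    homopolymer_bias: float = 0.7
    invariable_stretch: int = 548
    bin_width: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean coverage must be positive")
        n_variants = sum(sum(b) for *_, b in self.genes)
        n_events = sum(c for *_, c in self.composition)
        if n_events != n_variants:
            raise ValueError(
                f"composition plans {n_events} events but gene bins hold {n_variants}"
            )


@dataclass
class HetTruth:
    variants: list[dict]  # position, gene, type, seq, fraction
    genome: CircularGenome

    @property
    def positions(self) -> list[int]:
        return sorted(v["position"] for v in self.variants)

    def to_json(self) -> str:
        return json.dumps({"variants": self.variants}, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def save_vcf(self, path: str | Path, chrom: str = "chrM") -> None:
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={chrom},length={self.genome.length}>",
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Planted allele fraction">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        seq = self.genome.sequence
        for v in sorted(self.variants, key=lambda x: x["position"]):
            p = v["position"]
            anchor = seq[p - 1]
            if v["type"] == "+":
                ref, alt = anchor, anchor + v["seq"]
            elif v["type"] == "-":
                ref, alt = anchor + v["seq"], anchor
            else:
                ref, alt = anchor, v["seq"]
            lines.append(f"{chrom}\t{p}\t.\t{ref}\t{alt}\t.\tPASS\tAF={v['fraction']:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def _nb_coverage(rng: np.random.Generator, n: int, mean: float, sd: float,
                 floor: int) -> np.ndarray:
    if sd <= 0 or sd * sd <= mean:
        cov = np.full(n, int(round(mean)))
    else:
        var = sd * sd
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        cov = rng.negative_binomial(r, p, size=n)
    return np.maximum(cov, floor)


def generate_het_pileup(
    config: HetSimConfig = HetSimConfig(),
) -> tuple[list[PileupSite], CircularGenome, list[GeneAnnotation], HetTruth]:
    """Pileup over a synthetic mitogenome with planted heteroplasmic variants.

    Genes are laid out sequentially with intergenic spacers, one of them
    widened to hold a variant-free stretch of at least
    ``invariable_stretch`` bp.  Planted fractions are drawn inside each
    gene's target frequency bin (kept >= 6% so four supporting reads remain
    attainable at the coverage floor); single-base indels are embedded in a
    homopolymer run of their base with probability ``homopolymer_bias``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    total_genes = sum(g[2] for g in config.genes)
    n_gaps = len(config.genes) + 1
    big_gap = config.invariable_stretch + 20
    leftover = L - total_genes - big_gap
    if leftover < n_gaps - 1:
        raise ValueError("genome too short for the gene plan")
    spacer = leftover // (n_gaps - 1)

    genome = _draw_sequence(rng, L, MT_BASE_P)

    # lay out genes; the widened spacer sits after the 10th gene
    annotations: list[GeneAnnotation] = []
    cursor = spacer
    for gi, (name, group, length, _bins) in enumerate(config.genes):
        start, end = cursor + 1, cursor + length
        annotations.append(GeneAnnotation(name, group, ((start, end),)))
        cursor = end + (big_gap if gi == 9 else spacer)

    # shuffle the composition plan over the variant slots
    events: list[tuple[str, str]] = []
    for etype, seq, count in config.composition:
        events.extend([(etype, seq)] * count)
    rng.shuffle(events)

    truth_variants: list[dict] = []
    ei = 0
    for (name, _group, _length, bins), ann in zip(config.genes, annotations):
        start, end = ann.intervals[0]
        n_var = sum(bins)
        if n_var == 0:
            continue
        # distinct positions with >= 4 bp separation, away from the gene edge
        candidates = np.arange(start, end - 2)
        pos: list[int] = []
        attempts = 0
        while len(pos) < n_var:
            p = int(rng.choice(candidates))
            if all(abs(p - q) >= 4 for q in pos):
                pos.append(p)
            attempts += 1
            if attempts > 10000:
                raise RuntimeError(f"cannot place {n_var} variants in {name}")
        pos.sort()
        fractions: list[float] = []
        for bi, count in enumerate(bins):
            lo = bi * config.bin_width
            hi = (bi + 1) * config.bin_width
            lo = max(lo + 0.5, 6.0)
            fractions.extend(rng.uniform(lo, hi - 0.1, size=count) / 100.0)
        rng.shuffle(fractions)
        for p, f in zip(pos, fractions):
            etype, seq = events[ei]
            ei += 1
            if etype == "sub":
                seq = _TRANSITION[str(genome[p - 1])]
            else:
                if len(seq) == 1 and rng.random() < config.homopolymer_bias:
                    run = int(rng.integers(3, 7))
                    genome[p : min(p + run, L)] = seq
                if etype == "-":
                    # deletion sequence must match the reference downstream
                    genome[p : p + len(seq)] = list(seq)
            truth_variants.append(
                {"position": p, "gene": name, "type": etype, "seq": seq,
                 "fraction": round(float(f), 4)}
            )

    genome_str = "".join(genome)
    coverage = _nb_coverage(rng, L, config.mean_coverage, config.coverage_sd,
                            config.min_coverage)
    calls_by_pos: dict[int, dict[str, int]] = {}
    star_by_pos: dict[int, int] = {}
    for v in sorted(truth_variants, key=lambda x: x["position"]):
        p, f = v["position"], v["fraction"]
        cov = int(coverage[p - 1])
        support = int(round(f * cov)) if config.exact_counts else int(rng.binomial(cov, f))
        if support == 0:
            continue
        calls = calls_by_pos.setdefault(p, {})
        ref = genome_str[p - 1]
        if v["type"] == "sub":
            calls[v["seq"]] = support
        elif v["type"] == "+":
            calls[f"+{v['seq']}"] = support
        else:
            calls[f"-{v['seq']}"] = support
            for q in range(p + 1, p + 1 + len(v["seq"])):
                star_by_pos[q] = star_by_pos.get(q, 0) + support

    sites: list[PileupSite] = []
    err_p = config.error_rate
    for p in range(1, L + 1):
        cov = int(coverage[p - 1])
        ref = genome_str[p - 1]
        calls = dict(calls_by_pos.get(p, {}))
        non_ref_bases = sum(c for k, c in calls.items() if not k.startswith(("+", "-")))
        stars = min(star_by_pos.get(p, 0), cov - non_ref_bases)
        if stars:
            calls["*"] = stars
        if err_p > 0:
            n_err = int(rng.binomial(cov - non_ref_bases - stars, err_p))
            if n_err:
                b = str(rng.choice([x for x in "ACGT" if x != ref]))
                calls[b] = calls.get(b, 0) + n_err
                non_ref_bases += n_err
        calls[ref] = cov - non_ref_bases - stars
        sites.append(PileupSite(position=p, ref_base=ref, coverage=cov, base_calls=calls))

    genome_obj = CircularGenome("chrM", genome_str)
    return sites, genome_obj, annotations, HetTruth(variants=truth_variants, genome=genome_obj)
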