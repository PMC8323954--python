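"""Polymorphic-site detection and classification in multiple alignments.

An alignment column with two or more observed alleles (gap counts as an
allele, N is ignored) is a polymorphic site.  Each site gets a designated
reference allele — the majority allele, with an auditable tie-break for the
bi-allelic 50/50 case — so that variant alleles always have frequency <= 50%.
Sites are classified as transition-, transversion- and/or indel-containing,
summarised per gene as a variability index (VI = 100 x polymorphic sites /
length), and distributed over allele-frequency bins with one unit of weight
per site split equally among its variant alleles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genome_model import GAP, GeneAnnotation, Msa

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))

TRANSITION = "transition"
TRANSVERSION = "transversion"
INDEL = "indel"


class ConsistencyError(RuntimeError):
    """A designated variant exceeds 50% frequency — internal invariant broken."""


@dataclass
class PolymorphicSite:
    """One polymorphic alignment column (or genome locus).

    ``alleles`` maps each observed allele (A/C/G/T/-) to its count; N never
    appears (excluded from numerator and denominator).  After designation,
    ``reference_allele`` holds the majority allele and ``variant_alleles`` /
    ``variant_frequencies`` the rest, with frequencies over ``denominator``.
    """

    msa_column: int
    reference_position: int
    alleles: dict[str, int]
    denominator: int
    reference_allele: str | None = None
    variant_alleles: list[str] = field(default_factory=list)
    variant_frequencies: list[float] = field(default_factory=list)
    type_flags: frozenset[str] = frozenset()

    @property
    def n_variants(self) -> int:
        return len(self.variant_alleles)

    def frequency(self, allele: str) -> float:
        return self.alleles[allele] / self.denominator


def designate_reference(site: PolymorphicSite, reference_char: str | None = None) -> PolymorphicSite:
    """Choose the reference allele of a site; the rest become variants.

    The majority allele is the reference.  A bi-allelic 50/50 tie keeps a
    single variant: the allele carried by the alignment's coordinate-reference
    record wins the tie when it is one of the tied alleles, otherwise the
    lexicographically smaller allele is the reference.  Multi-allelic ties at
    the top use the same rule.
    """
    if len(site.alleles) < 2:
        raise ValueError("designation requires >= 2 alleles")
    top = max(site.alleles.values())
    tied = sorted(a for a, c in site.alleles.items() if c == top)
    if len(tied) > 1 and reference_char in tied:
        ref = reference_char
    else:
        ref = tied[0]
    site.reference_allele = ref
    variants = sorted(a for a in site.alleles if a != ref)
    site.variant_alleles = variants
    site.variant_frequencies = [site.alleles[a] / site.denominator for a in variants]
    return site


def classify_site(site: PolymorphicSite) -> frozenset[str]:
    """Type flags from every reference<->variant allele pair.

    Transition for A<->G / C<->T pairs, transversion for purine<->pyrimidine
    pairs, indel when a gap is involved; flags combine (e.g. a tri-allelic
    site can be transition- and transversion-containing at once).
    """
    if site.reference_allele is None:
        raise ValueError("site must have a designated reference allele")
    flags: set[str] = set()
    for v in site.variant_alleles:
        pair = frozenset((site.reference_allele, v))
        if GAP in pair:
            flags.add(INDEL)
        elif pair in TRANSITION_PAIRS:
            flags.add(TRANSITION)
        else:
            flags.add(TRANSVERSION)
    site.type_flags = frozenset(flags)
    return site.type_flags


def scan_sites(msa: Msa, gap_in_denominator: bool = True) -> list[PolymorphicSite]:
    """Scan every alignment column; return the polymorphic ones, designated
    and classified.

    N characters are dropped from both the allele counts and the frequency
    denominator; all-N columns are skipped.  With ``gap_in_denominator=False``
    gap characters still count as indel alleles but are removed from the
    denominator of substitution-allele frequencies' shared denominator
    (sequences carrying only a gap at the column are not "sampled" there).
    """
    arr = msa.as_array()
    coord = msa.coordinate_map()
    ref_row = msa.ids.index(msa.reference_id)
    offset = msa.reference_start - 1
    sites: list[PolymorphicSite] = []
    for j in range(msa.n_cols):
        col = arr[:, j]
        alleles, counts = np.unique(col[col != "N"], return_counts=True)
        if alleles.size < 2:
            continue
        allele_counts = {str(a): int(c) for a, c in zip(alleles, counts)}
        denom = int(counts.sum())
        if not gap_in_denominator and GAP in allele_counts:
            denom -= allele_counts[GAP]
            if denom == 0:
                continue
        site = PolymorphicSite(
            msa_column=j + 1,
            reference_position=int(coord[j]) + offset,
            alleles=allele_counts,
            denominator=denom,
        )
        ref_char = str(col[ref_row])
        designate_reference(site, reference_char=ref_char if ref_char != "N" else None)
        classify_site(site)
        sites.append(site)
    return sites


@dataclass(frozen=True)
class VariabilityIndex:
    """Polymorphic-site density of a region: VI = 100 x n / length (%)."""

    n_polymorphic: int
    length: int
    vi: float


def variability_index(n_polymorphic: int, length: int) -> VariabilityIndex:
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= n_polymorphic <= length:
        raise ValueError("n_polymorphic must lie in [0, length]")
    return VariabilityIndex(n_polymorphic, length, 100.0 * n_polymorphic / length)


class FreqBinTable:
    """Weighted variant counts per region over frequency intervals.

    Bins are left-open right-closed percentage intervals, e.g.
    ``(0, 10] (10, 20] ...``.  Each polymorphic site contributes total weight
    1, split equally among its variant alleles, so the grand total equals the
    number of contributing sites.
    """

    def __init__(
        self,
        bin_edges: list[tuple[float, float]],
        lengths: dict[str, float] | None = None,
        groups: dict[str, str] | None = None,
        labels: list[str] | None = None,
    ) -> None:
        self.bin_edges = [(float(lo), float(hi)) for lo, hi in bin_edges]
        self.rows: dict[str, np.ndarray] = {}
        self.lengths = dict(lengths or {})
        self.groups = dict(groups or {})
        self.site_counts: dict[str, float] = {}
        self._labels = labels

    @classmethod
    def with_width(cls, bin_width: float = 10.0, max_pct: float = 50.0, **kw) -> "FreqBinTable":
        n = int(round(max_pct / bin_width))
        edges = [(i * bin_width, (i + 1) * bin_width) for i in range(n)]
        return cls(edges, **kw)

    @property
    def bin_labels(self) -> list[str]:
        if self._labels is not None:
            return self._labels
        return [f"({lo:g}, {hi:g}]" for lo, hi in self.bin_edges]

    def bin_index(self, pct: float) -> int:
        for i, (lo, hi) in enumerate(self.bin_edges):
            if lo < pct <= hi + 1e-9:
                return i
        raise ValueError(f"frequency {pct}% outside bin range")

    def add(self, row: str, pct: float, weight: float = 1.0) -> None:
        arr = self.rows.setdefault(row, np.zeros(len(self.bin_edges)))
        arr[self.bin_index(pct)] += weight

    def count_site(self, row: str, n: float = 1.0) -> None:
        self.site_counts[row] = self.site_counts.get(row, 0.0) + n

    def row_total(self, row: str) -> float:
        return float(self.rows[row].sum())

    @property
    def column_totals(self) -> np.ndarray:
        if not self.rows:
            return np.zeros(len(self.bin_edges))
        return np.sum(list(self.rows.values()), axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.column_totals.sum())

    @property
    def relative_frequencies(self) -> np.ndarray:
        """Per-bin share of the grand total, in percent."""
        total = self.grand_total
        if total == 0:
            return np.zeros(len(self.bin_edges))
        return 100.0 * self.column_totals / total

    def vi(self, row: str) -> float:
        n = self.site_counts.get(row, self.row_total(row))
        return 100.0 * n / self.lengths[row]

    def to_frame(self, sort_by_vi: bool = False, decimals: int = 1) -> pd.DataFrame:
        recs = []
        for name, weights in self.rows.items():
            rec: dict = {"name": name}
            if self.groups:
                rec["group"] = self.groups.get(name, "")
            rec.update({lbl: round(w, decimals) for lbl, w in zip(self.bin_labels, weights)})
            rec["total"] = round(self.row_total(name), decimals)
            if name in self.lengths:
                rec["length_bp"] = self.lengths[name]
                rec["vi_pct"] = round(self.vi(name), 2)
            recs.append(rec)
        df = pd.DataFrame(recs)
        if sort_by_vi and "vi_pct" in df.columns:
            df = df.sort_values("vi_pct", ascending=False, ignore_index=True)
        return df


def weighted_bin_distribution(
    sites: list[PolymorphicSite],
    bin_width: float = 10.0,
    region_of=None,
    lengths: dict[str, float] | None = None,
) -> FreqBinTable:
    """Distribute sites over frequency bins, weighted 1/k per variant allele.

    ``region_of`` maps a site to its row name (default: a single ``all``
    row).  Raises :class:`ConsistencyError` if any designated variant exceeds
    50% — designation guarantees this cannot happen.
    """
    table = FreqBinTable.with_width(bin_width=bin_width, lengths=lengths)
    for site in sites:
        if not site.variant_alleles:
            raise ValueError("sites must have designated reference alleles")
        row = region_of(site) if region_of else "all"
        if row is None:
            continue
        k = site.n_variants
        for f in site.variant_frequencies:
            pct = 100.0 * f
            if pct > 50.0 + 1e-9:
                raise ConsistencyError(
                    f"variant frequency {pct:.1f}% > 50% at column {site.msa_column}"
                )
            table.add(row, pct, weight=1.0 / k)
        table.count_site(row)
    return table


def assign_gene(
    site: PolymorphicSite, annotations: list[GeneAnnotation], L: int | None = None
) -> list[str]:
    """Gene names containing the site's reference position; empty if intergenic."""
    hits = [a.gene_name for a in annotations if a.contains(site.reference_position, L)]
    if len(hits) > 1:
        warnings.warn(
            f"position {site.reference_position} overlaps genes {hits}; assigned to all",
            stacklevel=2,
        )
    return hits


def per_gene_variant_table(
    sites: list[PolymorphicSite],
    annotations: list[GeneAnnotation],
    n_seqs: int,
    L: int | None = None,
    include_intergenic: bool = False,
) -> FreqBinTable:
    """Per-gene variant counts by attainable frequency class (Table-4 style).

    With ``n_seqs`` sequences the attainable variant frequencies are
    ``k / n_seqs`` for k = 1 .. n_seqs//2 (a 50/50 split counts one variant);
    the bins are those exact classes.  Per-gene VI uses the polymorphic-site
    count over the gene length.
    """
    classes = [100.0 * k / n_seqs for k in range(1, n_seqs // 2 + 1)]
    edges = [(c - 1e-6, c) for c in classes]
    lengths = {a.gene_name: float(a.length(L)) for a in annotations}
    groups = {a.gene_name: a.gene_group for a in annotations}
    table = FreqBinTable(
        edges, lengths=lengths, groups=groups,
        labels=[f"{c:g}% frequency" for c in classes],
    )
    for site in sites:
        genes = assign_gene(site, annotations, L)
        if not genes:
            if not include_intergenic:
                continue
            genes = ["intergenic"]
            table.lengths.setdefault("intergenic", float("nan"))
            table.groups.setdefault("intergenic", "intergenic")
        for g in genes:
            for f in site.variant_frequencies:
                table.add(g, 100.0 * f, weight=1.0)
            table.count_site(g)
    return table


def site_type_tabulation(sites: list[PolymorphicSite]) -> dict[str, int]:
    """Counts of sites per (possibly combined) type category.

    Categories are the sorted '+'-joined flag sets, e.g. ``transition``,
    ``transition+transversion``, ``indel+transition`` — every site carries at
    least one flag, so the categories partition the sites.
    """
    out: dict[str, int] = {}
    for s in sites:
        if not s.type_flags:
            raise ConsistencyError(f"unclassified site at column {s.msa_column}")
        label = "+".join(sorted(s.type_flags))
        out[label] = out.get(label, 0) + 1
    return out


def sites_to_frame(sites: list[PolymorphicSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "msa_column": [s.msa_column for s in sites],
            "reference_position": [s.reference_position for s in sites],
            "reference_allele": [s.reference_allele for s in sites],
            "variant_alleles": [",".join(s.variant_alleles) for s in sites],
            "variant_frequencies": [
                ",".join(f"{100 * f:.1f}" for f in s.variant_frequencies) for s in sites
            ],
            "type_flags": ["+".join(sorted(s.type_flags)) for s in sites],
        }
    )


class PolymorphismScanner(BaseEstimator):
    """Detect, designate and classify polymorphic sites in an alignment.

    Parameters
    ----------
    gap_in_denominator : bool, default True
        Count gap-carrying sequences in the frequency denominator.
    bin_width : float, default 10.0
        Width (percent) of the frequency bins used by :meth:`bin_table`.

    Attributes
    ----------
    sites_ : list of PolymorphicSite
    n_seqs_, n_cols_ : alignment dimensions
    type_counts_ : dict, site-type tabulation
    """

    def __init__(self, gap_in_denominator: bool = True, bin_width: float = 10.0):
        self.gap_in_denominator = gap_in_denominator
        self.bin_width = bin_width

    def fit(self, msa: Msa, y=None) -> "PolymorphismScanner":
        if not isinstance(msa, Msa):
            raise TypeError("fit expects an Msa")
        self.sites_ = scan_sites(msa, gap_in_denominator=self.gap_in_denominator)
        self.n_seqs_ = msa.n_seqs
        self.n_cols_ = msa.n_cols
        self.type_counts_ = site_type_tabulation(self.sites_) if self.sites_ else {}
        logger.info("found %d polymorphic sites in %d columns", len(self.sites_), msa.n_cols)
        return self

    def bin_table(self, region_of=None, lengths=None) -> FreqBinTable:
        self._check_fitted()
        return weighted_bin_distribution(
            self.sites_, bin_width=self.bin_width, region_of=region_of, lengths=lengths
        )

    def gene_table(self, annotations: list[GeneAnnotation], L: int | None = None) -> FreqBinTable:
        self._check_fitted()
        return per_gene_variant_table(self.sites_, annotations, self.n_seqs_, L)

    def _check_fitted(self) -> None:
        if not hasattr(self, "sites_"):
            raise RuntimeError("scanner is not fitted; call fit(msa) first")
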