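"""Conserved and variable segment detection in control-region alignments.

A conserved segment (CS) is a maximal run of alignment columns, at least
``min_window`` long, in which the column conservation reaches the threshold
(at 100%: every sequence carries the same non-N base; a gap or N counts as a
mismatch).  Each run is tested against a hypergeometric window null — the
probability that a fixed window of its length contains none of the S
polymorphic columns placed uniformly among the L alignment columns,
C(L-w, S) / C(L, S) — and kept when p < alpha.  The complement of the kept
runs forms the variable segments (VS), which are grouped into hypervariable
regions at the valley between the two largest peaks of the per-VS
polymorphic-count profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genome_model import GAP, Msa
from .polymorphism import INDEL, PolymorphicSite, scan_sites

logger = logging.getLogger(__name__)

CONSERVED = "conserved"
VARIABLE = "variable"
HYPERVARIABLE = "hypervariable"


@dataclass
class Segment:
    """A CS/VS/HVS interval with its summary statistics.

    ``start``/``end`` are 1-based inclusive reference coordinates;
    ``col_start``/``col_end`` the corresponding alignment columns.  VI is only
    meaningful for variable segments (a conserved segment has zero polymorphic
    sites by construction at a 100% threshold).
    """

    label: str
    kind: str
    start: int
    end: int
    col_start: int
    col_end: int
    length: int = 0
    gc_content: float = float("nan")
    n_conserved_sites: int = 0
    n_polymorphic_sites: int = 0
    vi: float = float("nan")
    p_value: float | None = None
    members: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ConservationParams:
    """Window parameters of the conserved-region scan."""

    min_window: int = 20
    conservation_threshold: float = 100.0
    alpha: float = 0.05
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.min_window < 1:
            raise ValueError("min_window must be >= 1")
        if not 0 < self.conservation_threshold <= 100:
            raise ValueError("conservation_threshold must be in (0, 100]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def conserved_run_pvalue(w: int, S: int, L: int, bonferroni: bool = False) -> float:
    """P(a fixed window of length w holds 0 of S uniform polymorphic columns).

    Exact hypergeometric null: C(L-w, S) / C(L, S); 0 when the S columns
    cannot avoid the window, 1 when S = 0.  The optional Bonferroni variant
    multiplies by the number of window placements, L - w + 1 (capped at 1).
    """
    if not 1 <= w <= L:
        raise ValueError("window length must lie in [1, L]")
    if not 0 <= S <= L:
        raise ValueError("S must lie in [0, L]")
    if S == 0:
        return 1.0
    if S > L - w:
        return 0.0
    p = comb(L - w, S) / comb(L, S)
    if bonferroni:
        p = min(1.0, p * (L - w + 1))
    return p


def column_conservation(msa: Msa) -> np.ndarray:
    """Percent conservation per column: modal non-N, non-gap base count over
    n_seqs.  Gaps and N count against conservation."""
    arr = msa.as_array()
    n = msa.n_seqs
    out = np.empty(msa.n_cols)
    for j in range(msa.n_cols):
        col = arr[:, j]
        col = col[(col != "N") & (col != GAP)]
        if col.size == 0:
            out[j] = 0.0
        else:
            _, counts = np.unique(col, return_counts=True)
            out[j] = 100.0 * counts.max() / n
    return out


def find_conserved_segments(
    msa: Msa,
    params: ConservationParams = ConservationParams(),
    sites: list[PolymorphicSite] | None = None,
) -> list[Segment]:
    """Maximal conserved runs >= min_window with p < alpha, labelled CS1.. 5'->3'."""
    conservation = column_conservation(msa)
    if sites is None:
        sites = scan_sites(msa)
    S = len(sites)
    L = msa.n_cols
    ok = conservation >= params.conservation_threshold - 1e-9
    segments: list[Segment] = []
    j = 0
    while j < L:
        if ok[j]:
            start = j
            while j < L and ok[j]:
                j += 1
            w = j - start
            if w >= params.min_window:
                p = conserved_run_pvalue(w, S, L, bonferroni=params.bonferroni)
                # with S = 0 the window null is degenerate (p = 1); an
                # alignment without any polymorphism still reports its run
                if p < params.alpha or S == 0:
                    segments.append(
                        Segment(
                            label="",
                            kind=CONSERVED,
                            start=msa.ref_position(start + 1),
                            end=msa.ref_position(j),
                            col_start=start + 1,
                            col_end=j,
                            length=w,
                            p_value=p,
                        )
                    )
                else:
                    logger.info("dropped conserved run of %d columns (p = %.3g)", w, p)
        else:
            j += 1
    for i, seg in enumerate(segments, 1):
        seg.label = f"CS{i}"
    return segments


def derive_variable_segments(
    cs: list[Segment], cr_span: tuple[int, int], msa: Msa | None = None
) -> list[Segment]:
    """Complement of the conserved segments within the CR span (columns),
    labelled VS1.. 5'->3'; leading/trailing non-conserved stretches included."""
    lo, hi = cr_span
    cs = sorted(cs, key=lambda s: s.col_start)
    for a, b in zip(cs, cs[1:]):
        if b.col_start <= a.col_end:
            raise ValueError(f"overlapping conserved segments {a.label} and {b.label}")
    out: list[Segment] = []
    cursor = lo
    bounds = [(s.col_start, s.col_end) for s in cs] + [(hi + 1, hi + 1)]
    for cstart, cend in bounds:
        if cursor < cstart:
            a, b = cursor, cstart - 1
            out.append(
                Segment(
                    label="",
                    kind=VARIABLE,
                    start=msa.ref_position(a) if msa else a,
                    end=msa.ref_position(b) if msa else b,
                    col_start=a,
                    col_end=b,
                    length=b - a + 1,
                )
            )
        cursor = max(cursor, cend + 1)
    for i, seg in enumerate(out, 1):
        seg.label = f"VS{i}"
    return out


def segment_stats(
    segment: Segment, msa: Msa, sites: list[PolymorphicSite]
) -> Segment:
    """Fill length, GC, conserved/polymorphic site counts and VI for a segment.

    GC is computed over the non-gap, non-N characters of columns that are not
    indel-containing sites, pooled across sequences (matching the convention
    of ignoring gaps and indel sites).
    """
    if not 1 <= segment.col_start <= segment.col_end <= msa.n_cols:
        raise ValueError(f"segment {segment.label} outside alignment span")
    cols = slice(segment.col_start - 1, segment.col_end)
    arr = msa.as_array()[:, cols]
    in_seg = [s for s in sites if segment.col_start <= s.msa_column <= segment.col_end]
    indel_cols = {s.msa_column for s in in_seg if INDEL in s.type_flags}
    keep = np.array(
        [j + segment.col_start not in indel_cols for j in range(arr.shape[1])]
    )
    sub = arr[:, keep]
    bases = sub[(sub != GAP) & (sub != "N")]
    gc = 100.0 * np.isin(bases, ("G", "C")).sum() / bases.size if bases.size else float("nan")
    n_poly = len(in_seg)
    n_total = segment.col_end - segment.col_start + 1
    segment.length = n_total
    segment.gc_content = float(gc)
    segment.n_polymorphic_sites = n_poly
    segment.n_conserved_sites = n_total - n_poly
    segment.vi = 100.0 * n_poly / n_total if segment.kind != CONSERVED else float("nan")
    return segment


def _local_peaks(counts: np.ndarray) -> list[int]:
    peaks = []
    n = len(counts)
    for i in range(n):
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[i + 1] if i < n - 1 else -np.inf
        if counts[i] > left and counts[i] > right:
            peaks.append(i)
    return peaks


def group_hypervariable(
    vs: list[Segment],
    profile: list[int] | None = None,
    split_after: int | None = None,
) -> list[Segment]:
    """Partition ordered VS into contiguous hypervariable groups.

    The split falls at the minimum of the polymorphic-count profile between
    its two largest peaks (the valley segment starts the second group); a
    unimodal profile yields a single group with a warning.  ``split_after``
    (1-based VS index) overrides the automatic grouping.
    """
    if len(vs) < 2:
        raise ValueError("need at least 2 variable segments")
    counts = np.asarray(
        profile if profile is not None else [s.n_polymorphic_sites for s in vs], dtype=float
    )
    if split_after is not None:
        groups = [list(range(split_after)), list(range(split_after, len(vs)))]
    else:
        peaks = _local_peaks(counts)
        if len(peaks) < 2:
            warnings.warn("unimodal polymorphic-count profile; single hypervariable group")
            groups = [list(range(len(vs)))]
        else:
            p1, p2 = sorted(sorted(peaks, key=lambda i: -counts[i])[:2])
            valley = p1 + 1 + int(np.argmin(counts[p1 + 1 : p2]))
            groups = [list(range(valley)), list(range(valley, len(vs)))]
    out = []
    for i, idx in enumerate(g for g in groups if g):
        members = [vs[k] for k in idx]
        out.append(
            Segment(
                label=f"HVS{i + 1}",
                kind=HYPERVARIABLE,
                start=members[0].start,
                end=members[-1].end,
                col_start=members[0].col_start,
                col_end=members[-1].col_end,
                length=sum(m.length for m in members),
                n_polymorphic_sites=sum(m.n_polymorphic_sites for m in members),
                members=[m.label for m in members],
            )
        )
    return out


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Report in the Segment / Length / Start / End / GC / conserved /
    polymorphic / VI column order."""
    return pd.DataFrame(
        {
            "segment": [s.label for s in segments],
            "kind": [s.kind for s in segments],
            "length_bp": [s.length for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "gc_pct": [round(s.gc_content, 1) for s in segments],
            "conserved_sites": [s.n_conserved_sites for s in segments],
            "polymorphic_sites": [s.n_polymorphic_sites for s in segments],
            "vi_pct": [
                round(s.vi, 1) if s.vi == s.vi else float("nan") for s in segments
            ],
            "p_value": [s.p_value for s in segments],
        }
    )


def segments_to_bed(segments: list[Segment], chrom: str = "chrM") -> str:
    lines = [
        f"{chrom}\t{s.start - 1}\t{s.end}\t{s.label}" for s in segments
    ]
    return "\n".join(lines) + "\n"


class ConservedSegmentFinder(BaseEstimator):
    """Detect conserved segments and derive the variable-segment complement.

    Parameters mirror the window scan: ``min_window`` (bp), the column
    ``conservation_threshold`` (percent), the run-level significance ``alpha``
    and an optional Bonferroni correction over window placements.

    Attributes (after :meth:`fit`)
    ------------------------------
    sites_ : polymorphic sites of the alignment
    conserved_segments_, variable_segments_ : labelled, statistics filled
    segments_ : both, in positional order
    hypervariable_segments_ : contiguous VS groups (when >= 2 VS)
    """

    def __init__(
        self,
        min_window: int = 20,
        conservation_threshold: float = 100.0,
        alpha: float = 0.05,
        bonferroni: bool = False,
        hvs_split_after: int | None = None,
    ):
        self.min_window = min_window
        self.conservation_threshold = conservation_threshold
        self.alpha = alpha
        self.bonferroni = bonferroni
        self.hvs_split_after = hvs_split_after

    def fit(self, msa: Msa, y=None) -> "ConservedSegmentFinder":
        if not isinstance(msa, Msa):
            raise TypeError("fit expects an Msa")
        params = ConservationParams(
            min_window=self.min_window,
            conservation_threshold=self.conservation_threshold,
            alpha=self.alpha,
            bonferroni=self.bonferroni,
        )
        self.sites_ = scan_sites(msa)
        cs = find_conserved_segments(msa, params, sites=self.sites_)
        vs = derive_variable_segments(cs, (1, msa.n_cols), msa=msa)
        for seg in cs + vs:
            segment_stats(seg, msa, self.sites_)
        self.conserved_segments_ = cs
        self.variable_segments_ = vs
        self.segments_ = sorted(cs + vs, key=lambda s: s.col_start)
        if len(vs) >= 2:
            self.hypervariable_segments_ = group_hypervariable(
                vs, split_after=self.hvs_split_after
            )
        else:
            self.hypervariable_segments_ = []
        logger.info(
            "found %d conserved and %d variable segments (%d polymorphic sites)",
            len(cs), len(vs), len(self.sites_),
        )
        return self

    def table(self) -> pd.DataFrame:
        if not hasattr(self, "segments_"):
            raise RuntimeError("finder is not fitted; call fit(msa) first")
        ordered = self.variable_segments_ + self.conserved_segments_
        return segments_to_frame(ordered)
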