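"""Joint inter- vs intra-individual variability reports.

Joins per-gene/segment variability indices from the between-genome analysis
and the heteroplasmy analysis over a shared name universe, categorises each
entry (inter-only / intra-only / both / neither), and summarises the
variable-segment polymorphism profile with its peaks (the bimodal shape that
defines the two hypervariable regions).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

INTER_ONLY = "inter_only"
INTRA_ONLY = "intra_only"
BOTH = "both"
NEITHER = "neither"

# Canonical spellings for names the source tables write inconsistently.
_NAME_ALIASES = {
    "SRRNA": "s-rRNA",
    "S-RRNA": "s-rRNA",
    "12S": "s-rRNA",
    "LRRNA": "l-rRNA",
    "L-RRNA": "l-rRNA",
    "16S": "l-rRNA",
    "COB": "CYTB",
    "CYTB GENE": "CYTB",
}


def normalize_name(name: str) -> str:
    """Canonical gene/segment name: collapse spacing ('VS 3' -> 'VS3'),
    drop a trailing 'gene', map rRNA spelling variants."""
    s = re.sub(r"\s+", " ", name.strip())
    s = re.sub(r"\s*gene$", "", s, flags=re.IGNORECASE)
    s = re.sub(r"^(VS|CS|HVS)\s+(\d)", r"\1\2", s, flags=re.IGNORECASE)
    key = s.upper().replace(" ", "")
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key]
    if re.fullmatch(r"(vs|cs|hvs)\d+", s, flags=re.IGNORECASE):
        return s.upper()
    if re.fullmatch(r"(nd\d+l?|cox\d+|atp\d+|cytb)", s, flags=re.IGNORECASE):
        return s.upper()
    return s


@dataclass(frozen=True)
class ComparisonRow:
    """One gene/segment with its inter- and intra-individual VI."""

    name: str
    gene_group: str
    vi_inter: float | None
    vi_intra: float | None
    category: str
    vi_sum: float


def join_vi_tables(
    inter: dict[str, float],
    intra: dict[str, float],
    universe: list[str],
    groups: dict[str, str] | None = None,
) -> list[ComparisonRow]:
    """One row per universe entry with its presence category and VI sum.

    Names are normalised before matching; a VI-table name missing from the
    universe is a validation error (listing the offenders), so silent drops
    cannot happen.
    """
    groups = groups or {}
    uni = {normalize_name(n): n for n in universe}
    inter_n = {normalize_name(k): v for k, v in inter.items()}
    intra_n = {normalize_name(k): v for k, v in intra.items()}
    stray = sorted((set(inter_n) | set(intra_n)) - set(uni))
    if stray:
        raise ValueError(f"names absent from the universe: {stray}")
    rows: list[ComparisonRow] = []
    for key, name in uni.items():
        vi_i = inter_n.get(key)
        vi_h = intra_n.get(key)
        if vi_i is not None and vi_h is not None:
            cat = BOTH
        elif vi_i is not None:
            cat = INTER_ONLY
        elif vi_h is not None:
            cat = INTRA_ONLY
        else:
            cat = NEITHER
        rows.append(
            ComparisonRow(
                name=name,
                gene_group=groups.get(name, groups.get(key, "")),
                vi_inter=vi_i,
                vi_intra=vi_h,
                category=cat,
                vi_sum=(vi_i or 0.0) + (vi_h or 0.0),
            )
        )
    rows.sort(key=lambda r: -r.vi_sum)
    return rows


def category_counts(rows: list[ComparisonRow]) -> dict[str, int]:
    out = {INTER_ONLY: 0, INTRA_ONLY: 0, BOTH: 0, NEITHER: 0}
    for r in rows:
        out[r.category] += 1
    return out


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in rows],
            "group": [r.gene_group for r in rows],
            "vi_inter_pct": [None if r.vi_inter is None else round(r.vi_inter, 2) for r in rows],
            "vi_intra_pct": [None if r.vi_intra is None else round(r.vi_intra, 2) for r in rows],
            "category": [r.category for r in rows],
            "vi_sum_pct": [round(r.vi_sum, 2) for r in rows],
        }
    )


def vs_profile(counts: list[int]) -> tuple[np.ndarray, list[int]]:
    """Ordered per-VS polymorphic counts plus detected peak indices (0-based).

    A strict local maximum (edges compared against their single neighbour)
    is a peak; a flat profile has none and warns.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty profile")
    peaks: list[int] = []
    for i in range(arr.size):
        left = arr[i - 1] if i > 0 else -np.inf
        right = arr[i + 1] if i < arr.size - 1 else -np.inf
        if arr[i] > left and arr[i] > right:
            peaks.append(i)
    if not peaks:
        warnings.warn("flat polymorphic-count profile: no strict peak")
    return arr, peaks


def plot_profile(counts: list[int], labels: list[str] | None = None, path=None):
    """Bar plot of the VS polymorphism profile with peaks marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr, peaks = vs_profile(counts)
    labels = labels or [f"VS{i + 1}" for i in range(len(counts))]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = ["#d62728" if i in peaks else "#1f77b4" for i in range(len(counts))]
    ax.bar(labels, arr, color=colors)
    ax.set_ylabel("polymorphic sites")
    ax.set_xlabel("variable segment")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
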