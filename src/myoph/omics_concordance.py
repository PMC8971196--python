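"""Cross-omics integration statistics.

Implements the quantitative layer linking pH-responsive transcripts (DEGs),
proteins (DAPs) and H3K27ac chromatin peaks:

* Benjamini–Hochberg FDR adjustment and the padj < alpha / sign(log2FC)
  classification into down- and up-regulated feature sets;
* the DEG↔DAP direction-concordance 2×2 table and Fisher's exact test
  (two-sided, by hypergeometric enumeration over the margin-fixed support);
* peak-presence summaries against the union peak set ("present in at least
  one experimental group"), with percentages rounded to the nearest integer
  (ties away from zero) exactly as printed figures are derived;
* promoter-overlap fractions of gene TSS windows against peak intervals
  (0-based half-open coordinates throughout);
* ChIP spike-in (dm6:rn6) scale factors for reference normalisation.

Differential statistics themselves (DESeq2 / DEP) are upstream of this
module; their output tables are its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "bh_adjust",
    "classify_features",
    "concordance_table",
    "fisher_exact_2x2",
    "summarize_peak_presence",
    "promoter_overlap_fraction",
    "spike_in_scale_factor",
    "percent_rounded",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = DEG direction (down/up), cols = DAP direction."""

    a: int  # gene down, protein down
    b: int  # gene down, protein up
    c: int  # gene up, protein down
    d: int  # gene up, protein up

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one pair")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_features(
    table: pd.DataFrame, alpha: float = 0.05
) -> Tuple[Set[str], Set[str]]:
    """Split a differential table into (down, up) significant id sets.

    Significance is ``padj < alpha`` (the padj column is computed by
    :func:`bh_adjust` from ``pvalue`` when absent); direction is the sign of
    ``log2fc``.  Significant features with exactly zero fold-change carry no
    direction and are excluded.
    """
    if table.empty:
        return set(), set()
    padj = (
        np.asarray(table["padj"], dtype=float)
        if "padj" in table.columns
        else bh_adjust(np.asarray(table["pvalue"], dtype=float))
    )
    lfc = np.asarray(table["log2fc"], dtype=float)
    ids = np.asarray(table["id"])
    sig = padj < alpha
    down = set(ids[sig & (lfc < 0)])
    up = set(ids[sig & (lfc > 0)])
    n_zero = int((sig & (lfc == 0)).sum())
    if n_zero:
        import warnings

        warnings.warn(
            f"{n_zero} significant feature(s) with log2FC == 0 excluded "
            "(no direction)",
            stacklevel=2,
        )
    return down, up


def concordance_table(
    gene_down: Set[str],
    gene_up: Set[str],
    prot_down: Iterable[str],
    prot_up: Iterable[str],
    id_map: Optional[Mapping[str, str]] = None,
) -> Tuple[ContingencyTable2x2, float, pd.DataFrame]:
    """DEG↔DAP direction-concordance 2×2 table over doubly significant pairs.

    Only features significant in *both* layers are counted.  ``id_map`` maps
    protein ids to gene ids (identity by default); duplicate protein entries
    are an error.  Returns (table, odds ratio, matched-pair DataFrame).
    """
    prot_down = list(prot_down)
    prot_up = list(prot_up)
    all_prot = prot_down + prot_up
    if len(all_prot) != len(set(all_prot)):
        raise ValueError("duplicate protein ids across direction sets")
    if id_map is not None and len(set(id_map.keys())) != len(id_map):
        raise ValueError("duplicate protein ids in id_map")

    def to_gene(pid: str) -> str:
        return id_map[pid] if id_map is not None and pid in id_map else pid

    a = b = c = d = 0
    pairs = []
    for pid, pdir in [(p, "down") for p in prot_down] + [
        (p, "up") for p in prot_up
    ]:
        gid = to_gene(pid)
        if gid in gene_down:
            gdir = "down"
        elif gid in gene_up:
            gdir = "up"
        else:
            continue
        if gdir == "down" and pdir == "down":
            a += 1
        elif gdir == "down" and pdir == "up":
            b += 1
        elif gdir == "up" and pdir == "down":
            c += 1
        else:
            d += 1
        pairs.append(dict(gene=gid, protein=pid, deg_dir=gdir, dap_dir=pdir))
    table = ContingencyTable2x2(a, b, c, d)
    return table, table.odds_ratio, pd.DataFrame(
        pairs, columns=["gene", "protein", "deg_dir", "dap_dir"]
    )


def fisher_exact_2x2(t: ContingencyTable2x2, *, slack: float = 1e-12) -> float:
    """Two-sided Fisher exact p-value by margin-fixed enumeration.

    Sums hypergeometric probabilities of every table sharing the observed
    margins whose probability is at most that of the observed table, with a
    relative numerical slack for floating-point ties.
    """
    N = t.total
    r1 = t.a + t.b
    c1 = t.a + t.c
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    p_obs = pmf[support == t.a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + slack)].sum())
    return min(1.0, p)


def percent_rounded(count: float, total: float) -> int:
    """Percentage rounded to the nearest integer, ties away from zero."""
    if total <= 0:
        raise ValueError("total must be > 0")
    x = 100.0 * count / total
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_peak_presence(
    peaks: pd.DataFrame, condition_cols: Optional[Sequence[str]] = None
) -> Dict[str, object]:
    """Per-condition counts and percentages against the union peak set.

    ``peaks`` has interval columns (chrom, start, end) plus one boolean
    presence column per condition.  Every row must be present in at least one
    condition (by construction of a union peak set).  Returns a dict:
    ``{"union": N, "conditions": {name: {"count", "percent", "percent_raw"}}}``.
    """
    if peaks.empty:
        raise ValueError("peak table is empty")
    if condition_cols is None:
        condition_cols = [
            c for c in peaks.columns if c not in ("chrom", "start", "end")
        ]
    if not condition_cols:
        raise ValueError("no condition columns found")
    if {"start", "end"}.issubset(peaks.columns):
        if (peaks["start"] >= peaks["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")
    flags = peaks[list(condition_cols)].to_numpy(dtype=bool)
    if not flags.any(axis=1).all():
        bad = int((~flags.any(axis=1)).sum())
        raise ValueError(
            f"{bad} peak(s) absent in all conditions; union construction violated"
        )
    union = int(len(peaks))
    conditions = {}
    for j, name in enumerate(condition_cols):
        count = int(flags[:, j].sum())
        conditions[name] = {
            "count": count,
            "percent": percent_rounded(count, union),
            "percent_raw": 100.0 * count / union,
        }
    return {"union": union, "conditions": conditions}


def promoter_overlap_fraction(
    tss_table: pd.DataFrame,
    peaks: pd.DataFrame,
    *,
    window_bp: int = 2000,
    condition: Optional[str] = None,
) -> Tuple[float, pd.DataFrame]:
    """Fraction of genes with >= 1 peak in their promoter window.

    The promoter window is the half-open interval [TSS − w, TSS + w), start
    clipped at zero, with 0-based TSS coordinates.  If ``condition`` is
    given, only peaks flagged present in that condition count; otherwise
    peaks present in any condition count.  Returns (fraction, per-gene
    flags DataFrame).
    """
    if tss_table.empty:
        raise ValueError("gene set is empty")
    use = peaks
    if condition is not None:
        if condition not in peaks.columns:
            raise ValueError(f"condition column {condition!r} not in peak table")
        use = peaks[peaks[condition].astype(bool)]

    trees: Dict[str, IntervalTree] = {}
    for chrom, grp in use.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[chrom] = tree

    flags = []
    for _, row in tss_table.iterrows():
        tss = int(row["tss"])
        start = max(0, tss - window_bp)
        end = tss + window_bp
        tree = trees.get(row["chrom"])
        hit = bool(tree.overlap(start, end)) if tree is not None else False
        flags.append(dict(gene=row["gene"], promoter_has_peak=hit))
    flag_df = pd.DataFrame(flags)
    return float(flag_df["promoter_has_peak"].mean()), flag_df


def spike_in_scale_factor(
    dm6_ip: float, rn6_ip: float, dm6_input: float, rn6_input: float
) -> float:
    """ChIP spike-in scale factor from dm6:rn6 read counts.

    factor = (dm6_input / rn6_input) / (dm6_ip / rn6_ip); multiplying IP
    coverage by the factor equalises exogenous-genome recovery relative to
    input across samples, making signal comparable between conditions.
    """
    counts = dict(
        dm6_ip=dm6_ip, rn6_ip=rn6_ip, dm6_input=dm6_input, rn6_input=rn6_input
    )
    for name, v in counts.items():
        if not v > 0:
            raise ValueError(f"read count {name} must be > 0, got {v}")
    return (dm6_input / rn6_input) / (dm6_ip / rn6_ip)
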