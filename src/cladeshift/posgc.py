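"""Codon-position splits, 2nd:3rd-position branch-length ratios, and GC content.

Second codon positions change amino acids almost always and third positions
rarely, so the per-branch ratio of 2nd- to 3rd-position branch lengths is a
model-free surrogate for dN/dS; comparing that ratio between within-unit and
among-unit branches with a one-way ANOVA cross-checks the branch-site model.
GC content by codon position separates selective from mutational explanations
of among-unit composition differences: mutation or gene-conversion bias should
show most strongly at third positions, selection on amino acids at second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon import Alignment, CodonAlignment
from .models import SiteClassification
from .trees import BranchLabeling, PhyloTree

logger = logging.getLogger("cladeshift")

#: Floor applied to 3rd-position branch lengths when forming ratios.
RATIO_FLOOR = 1e-6


def split_codon_positions(aln: CodonAlignment) -> tuple[Alignment, Alignment, Alignment]:
    """Three nucleotide alignments holding codon positions 1, 2 and 3."""
    outs = []
    for k in range(3):
        outs.append(Alignment(aln.names, [s[k::3] for s in aln.seqs]))
    return tuple(outs)


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    r_squared: float
    p_value: float
    group_means: dict[str, float]

    def __repr__(self) -> str:
        return (f"AnovaResult(F_{self.df1},{self.df2}={self.F:.3g}, "
                f"R2={self.r_squared:.3g}, p={self.p_value:.3g})")


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA: F = (SSB/df1)/(SSW/df2), R^2 = SSB/SST."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA requires at least two groups")
    grand = values.mean()
    ssb = ssw = 0.0
    means = {}
    for g in labels:
        v = values[groups == g]
        means[str(g)] = float(v.mean())
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += float(((v - v.mean()) ** 2).sum())
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    sst = ssb + ssw
    r2 = ssb / sst if sst > 0 else 0.0
    if df2 <= 0 or ssw == 0:
        F = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        F = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, float(r2), p, means)


# ---------------------------------------------------------------------------
# Branch-ratio analysis
# ---------------------------------------------------------------------------

@dataclass
class BranchRatioTable:
    """Per-branch 2nd/3rd-position lengths and their within/among ANOVA."""

    table: pd.DataFrame
    anova: AnovaResult

    def group_mean(self, flag: str) -> float:
        return self.anova.group_means[flag]


def branch_ratio_analysis(tree2: PhyloTree, tree3: PhyloTree,
                          labeling: BranchLabeling,
                          floor: float = RATIO_FLOOR) -> BranchRatioTable:
    """Ratio of 2nd- to 3rd-position branch lengths per branch, compared
    between foreground (among-unit) and background (within-unit) branches.

    The two trees must share the topology (identical tip sets below every
    node); near-zero 3rd-position branches are floored at ``floor``
    substitutions/site and flagged.
    """
    if tree2.tipsets() != tree3.tipsets():
        raise ValueError("2nd- and 3rd-position trees differ in topology")
    rows = []
    for v in tree2.branches():
        b2 = float(tree2.lengths[v])
        b3 = float(tree3.lengths[v])
        denom = max(b3, floor)
        rows.append({
            "branch": v,
            "parent": int(tree2.parent[v]),
            "clade_tips": ",".join(sorted(tree2.tipsets()[v])),
            "length_pos2": b2,
            "length_pos3": b3,
            "ratio": b2 / denom,
            "floored": b3 < floor,
            "label": labeling.flag(v),
        })
    df = pd.DataFrame(rows)
    res = one_way_anova(df["ratio"].to_numpy(), df["label"].to_numpy())
    return BranchRatioTable(df, res)


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def _gc_percent(seq: str) -> float:
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())  # gaps/ambiguity excluded
    if denom == 0:
        return np.nan
    return 100.0 * (counts["G"] + counts["C"]) / denom


def gc_content(aln: CodonAlignment,
               site_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-taxon GC percent at codon positions 1..3 and overall.

    ``site_mask`` (boolean per codon) restricts the computation to a codon
    subset, e.g. the high-posterior class-2a sites.  Denominators exclude
    gaps and ambiguity codes.
    """
    if site_mask is not None:
        site_mask = np.asarray(site_mask, dtype=bool)
        if site_mask.shape != (aln.n_codons,):
            raise ValueError("site_mask must have one entry per codon")
        if not site_mask.any():
            logger.warning("empty codon subset for GC profile")
            return pd.DataFrame(columns=["gc1", "gc2", "gc3", "gc_all"])
        keep = np.where(site_mask)[0]
        seqs = ["".join(s[3 * c: 3 * c + 3] for c in keep) for s in aln.seqs]
    else:
        seqs = aln.seqs
    rows = {}
    for name, seq in zip(aln.names, seqs):
        rows[name] = {
            "gc1": _gc_percent(seq[0::3]),
            "gc2": _gc_percent(seq[1::3]),
            "gc3": _gc_percent(seq[2::3]),
            "gc_all": _gc_percent(seq),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def class2a_gc_summary(aln: CodonAlignment, classification: SiteClassification,
                       threshold: float = 0.95) -> pd.DataFrame:
    """GC profile restricted to codons assigned to class 2a with posterior
    above ``threshold``."""
    post = classification.prob("2a")
    return gc_content(aln, site_mask=post > threshold)


def gc_anova_by_unit(profile: pd.DataFrame, unit_of: dict[str, str],
                     column: str = "gc2") -> AnovaResult:
    """ANOVA of a per-taxon GC column across units."""
    taxa = [t for t in profile.index if t in unit_of]
    vals = profile.loc[taxa, column].to_numpy()
    groups = np.array([unit_of[t] for t in taxa])
    return one_way_anova(vals, groups)
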