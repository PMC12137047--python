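"""Alignment-cleaning and paralog-filtering cascade for orthogroups.

The cascade mirrors standard practice when preparing codon alignments for
selection analyses: keep orthogroups of workable size with every unit
represented, discard identical and very gappy sequences, strip codon columns
containing gaps, extract the most nested subclade containing all units (to
shed ancient paralogs), keep one sequence per species (recent paralogs),
discard the most divergent orthogroups, and finally concatenate the groups
with full species coverage.  Every removal is logged in a
:class:`FilterReport` whose counts reconcile exactly with input/output sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import CodonAlignment
from .trees import PhyloTree, extract_subtree, max_branch_length, prune_tree


@dataclass
class Orthogroup:
    """A codon alignment with its gene tree and per-sequence labels."""

    id: str
    alignment: CodonAlignment
    tree: PhyloTree
    species: dict[str, str]  # sequence name -> species
    units: dict[str, str]    # sequence name -> unit (higher taxon)

    def __post_init__(self):
        aln_names = set(self.alignment.names)
        tree_names = set(self.tree.tip_name.values())
        if aln_names != tree_names:
            raise ValueError(
                f"orthogroup {self.id}: alignment/tree name mismatch: "
                f"{sorted(aln_names ^ tree_names)}")
        for name in self.alignment.names:
            if name not in self.species or name not in self.units:
                raise ValueError(f"orthogroup {self.id}: no label for {name!r}")

    @property
    def n_seqs(self) -> int:
        return self.alignment.n_seqs

    def restricted(self, keep: list[str], tree: PhyloTree | None = None) -> "Orthogroup":
        return Orthogroup(
            self.id,
            CodonAlignment(keep, [self.alignment.sequence(n) for n in keep],
                           code=self.alignment.code),
            tree if tree is not None else prune_tree(self.tree, set(keep)),
            {n: self.species[n] for n in keep},
            {n: self.units[n] for n in keep},
        )


@dataclass
class FilterReport:
    """Per-step removal log across a batch of orthogroups."""

    records: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def log(self, orthogroup: str, step: str, *, n_before: int, n_after: int,
            removed: list[str] | None = None, reason: str = "") -> None:
        rec = {"orthogroup": orthogroup, "step": step, "n_before": n_before,
               "n_after": n_after, "n_removed": n_before - n_after,
               "removed": ";".join(removed or []), "reason": reason}
        if rec["n_removed"] != len(removed or []) and removed is not None:
            raise ValueError("removal count does not reconcile with removed list")
        self.records.append(rec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["orthogroup", "step", "n_before",
                                     "n_after", "n_removed", "removed", "reason"])

    def reconciles(self) -> bool:
        """Within each orthogroup, successive steps must chain exactly."""
        df = self.to_frame()
        for og, sub in df.groupby("orthogroup", sort=False):
            seq_steps = sub[~sub["step"].str.contains("column")]
            chain = seq_steps[["n_before", "n_after"]].to_numpy()
            for prev, nxt in zip(chain[:-1, 1], chain[1:, 0]):
                if prev != nxt:
                    return False
        return True


# ---------------------------------------------------------------------------
# Step 0: orthogroup selection
# ---------------------------------------------------------------------------

def select_orthogroups(groups: list[Orthogroup], required_units: list[str],
                       min_seqs: int = 10, max_seqs: int = 100,
                       report: FilterReport | None = None) -> list[Orthogroup]:
    """Keep orthogroups with min_seqs..max_seqs sequences (inclusive) and at
    least one sequence from every required unit."""
    kept = []
    for og in groups:
        units_present = set(og.units.values())
        ok = (min_seqs <= og.n_seqs <= max_seqs
              and all(u in units_present for u in required_units))
        if ok:
            kept.append(og)
        elif report is not None:
            why = ("size out of range" if not min_seqs <= og.n_seqs <= max_seqs
                   else "missing unit(s): "
                        + ",".join(sorted(set(required_units) - units_present)))
            report.log(og.id, "select", n_before=og.n_seqs, n_after=0,
                       removed=list(og.alignment.names), reason=why)
    return kept


# ---------------------------------------------------------------------------
# Step 1: sequence-level cleaning
# ---------------------------------------------------------------------------

def drop_gappy_and_duplicate_sequences(
        aln: CodonAlignment, max_gap_fraction: float = 0.66) -> tuple[CodonAlignment, list[str]]:
    """Drop exact-duplicate sequences (first occurrence kept) and sequences
    whose gap fraction exceeds ``max_gap_fraction`` strictly.

    Gap fractions count nucleotide positions including terminal gaps;
    duplicates are compared on the full (gapped) strings.
    """
    removed: list[str] = []
    seen: set[str] = set()
    keep: list[str] = []
    for name, seq in zip(aln.names, aln.seqs):
        gap_frac = seq.count("-") / len(seq) if seq else 0.0
        if seq in seen:
            removed.append(name)
        elif gap_frac > max_gap_fraction:
            removed.append(name)
        else:
            seen.add(seq)
            keep.append(name)
    if not keep:
        raise ValueError("no sequences left after gap/duplicate filtering")
    out = CodonAlignment(keep, [aln.sequence(n) for n in keep], code=aln.code)
    return out, removed


def strip_gap_codon_columns(aln: CodonAlignment) -> tuple[CodonAlignment, list[int]]:
    """Delete every codon column containing a gap in any sequence.

    Returns the gap-free alignment and the removed 0-based codon column
    indices.  Raises if no columns survive.
    """
    removed = [
        s for s in range(aln.n_codons)
        if any("-" in seq[3 * s: 3 * s + 3] for seq in aln.seqs)
    ]
    if len(removed) == aln.n_codons:
        raise ValueError("no codon columns left after gap-column stripping")
    keep = [s for s in range(aln.n_codons) if s not in set(removed)]
    seqs = ["".join(seq[3 * s: 3 * s + 3] for s in keep) for seq in aln.seqs]
    return CodonAlignment(aln.names, seqs, code=aln.code), removed


# ---------------------------------------------------------------------------
# Step 2: paralog handling
# ---------------------------------------------------------------------------

def extract_nested_subclade(tree: PhyloTree, unit_of: dict[str, str],
                            required_units: list[str]) -> tuple[PhyloTree, list[str]]:
    """The most nested clade containing at least one tip of every unit.

    "Most nested" means smallest tip count; ties break on the
    lexicographically smallest sorted tip-label tuple.  If only the root
    qualifies, the whole tree is returned.
    """
    tipsets = tree.tipsets()
    required = set(required_units)
    candidates = []
    for v in range(tree.n_nodes):
        units_below = {unit_of[t] for t in tipsets[v]}
        if required <= units_below:
            candidates.append(v)
    if not candidates:
        raise ValueError("no clade (not even the root) contains all units")
    best = min(candidates,
               key=lambda v: (len(tipsets[v]), tuple(sorted(tipsets[v]))))
    retained = sorted(tipsets[best])
    if best == tree.root:
        return tree, retained
    return extract_subtree(tree, best), retained


def dedupe_within_species(aln: CodonAlignment, tree: PhyloTree,
                          species_of: dict[str, str],
                          seed: int = 0) -> tuple[CodonAlignment, PhyloTree, list[str]]:
    """Keep exactly one sequence per species, chosen uniformly at random
    (reproducible under ``seed``)."""
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[str]] = {}
    for name in aln.names:
        by_species.setdefault(species_of[name], []).append(name)
    keep: set[str] = set()
    for sp in sorted(by_species):
        copies = sorted(by_species[sp])
        keep.add(copies[int(rng.integers(len(copies)))])
    removed = [n for n in aln.names if n not in keep]
    kept_names = [n for n in aln.names if n in keep]
    out = CodonAlignment(kept_names, [aln.sequence(n) for n in kept_names],
                         code=aln.code)
    out_tree = prune_tree(tree, keep) if removed else tree
    return out, out_tree, removed


# ---------------------------------------------------------------------------
# Step 3: divergence filter (batch level)
# ---------------------------------------------------------------------------

def filter_top_divergent(groups: list[Orthogroup], fraction: float = 0.05,
                         min_seqs: int = 10,
                         report: FilterReport | None = None) -> list[Orthogroup]:
    """Discard the top ``ceil(fraction * N)`` orthogroups by maximum branch
    length, then any left with fewer than ``min_seqs`` sequences."""
    if not groups:
        return []
    scored = sorted(groups, key=lambda og: (-max_branch_length(og.tree), og.id))
    n_cut = math.ceil(fraction * len(groups))
    cut, rest = scored[:n_cut], scored[n_cut:]
    if report is not None:
        for og in cut:
            report.log(og.id, "divergence", n_before=og.n_seqs, n_after=0,
                       reason=f"top {fraction:.0%} by max branch length "
                              f"({max_branch_length(og.tree):.4g})")
    kept = []
    for og in sorted(rest, key=lambda og: og.id):
        if og.n_seqs < min_seqs:
            if report is not None:
                report.log(og.id, "min-seqs", n_before=og.n_seqs, n_after=0,
                           reason=f"fewer than {min_seqs} sequences")
        else:
            kept.append(og)
    return kept


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate(groups: list[Orthogroup],
                taxa: list[str]) -> tuple[CodonAlignment, pd.DataFrame]:
    """Concatenate the orthogroups with a sequence for every species in
    ``taxa`` (one per species), in stable orthogroup-id order.

    Rows of the result are species.  The returned partition map gives each
    orthogroup's 1-based inclusive nucleotide column range.
    """
    full = []
    for og in sorted(groups, key=lambda og: og.id):
        species = list(og.species.values())
        if sorted(species) == sorted(taxa):
            full.append(og)
        elif set(species) >= set(taxa):
            raise ValueError(
                f"orthogroup {og.id} has duplicate species; dedupe first")
    if not full:
        raise ValueError("no orthogroup covers all species; nothing to concatenate")
    parts: dict[str, list[str]] = {sp: [] for sp in taxa}
    rows = []
    start = 1
    for og in full:
        seq_of_species = {og.species[n]: og.alignment.sequence(n)
                          for n in og.alignment.names}
        for sp in taxa:
            parts[sp].append(seq_of_species[sp])
        end = start + og.alignment.length - 1
        rows.append({"orthogroup": og.id, "start": start, "end": end})
        start = end + 1
    aln = CodonAlignment(list(taxa), ["".join(parts[sp]) for sp in taxa])
    return aln, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def filter_orthogroup(og: Orthogroup, required_units: list[str], seed: int = 0,
                      max_gap_fraction: float = 0.66,
                      report: FilterReport | None = None) -> Orthogroup | None:
    """Run the per-orthogroup steps: sequence cleaning, gap-column stripping,
    nested-subclade extraction, within-species dedupe.

    Returns None (with a report entry) when an orthogroup collapses.
    """
    rep = report if report is not None else FilterReport()
    try:
        aln, dropped = drop_gappy_and_duplicate_sequences(og.alignment,
                                                          max_gap_fraction)
        rep.log(og.id, "gappy/duplicate", n_before=og.n_seqs,
                n_after=aln.n_seqs, removed=dropped,
                reason=f"identical or >{max_gap_fraction:.0%} gaps")
        if aln.n_seqs < 2:
            rep.log(og.id, "collapsed", n_before=aln.n_seqs, n_after=0,
                    reason="fewer than 2 sequences")
            return None
        tree = prune_tree(og.tree, set(aln.names)) if dropped else og.tree
        aln, cols = strip_gap_codon_columns(aln)
        rep.log(og.id, "gap-columns", n_before=aln.n_codons + len(cols),
                n_after=aln.n_codons,
                removed=[str(c) for c in cols], reason="codon column with gap")
        sub_tree, retained = extract_nested_subclade(
            tree, og.units, required_units)
        rep.log(og.id, "nested-subclade", n_before=aln.n_seqs,
                n_after=len(retained),
                removed=[n for n in aln.names if n not in set(retained)],
                reason="outside most nested all-unit clade")
        aln = CodonAlignment(retained, [aln.sequence(n) for n in retained],
                             code=aln.code)
        aln, sub_tree, dup_removed = dedupe_within_species(
            aln, sub_tree, og.species, seed=seed)
        rep.log(og.id, "species-dedupe", n_before=len(retained),
                n_after=aln.n_seqs, removed=dup_removed,
                reason="duplicate copy within species")
    except ValueError as exc:
        rep.log(og.id, "collapsed", n_before=og.n_seqs, n_after=0,
                reason=str(exc))
        return None
    return Orthogroup(og.id, aln, sub_tree,
                      {n: og.species[n] for n in aln.names},
                      {n: og.units[n] for n in aln.names})


def filter_batch(groups: list[Orthogroup], required_units: list[str],
                 seed: int = 0, min_seqs: int = 10, max_seqs: int = 100,
                 divergence_fraction: float = 0.05) -> tuple[list[Orthogroup], FilterReport]:
    """The whole cascade over a batch of orthogroups."""
    report = FilterReport(thresholds={
        "min_seqs": min_seqs, "max_seqs": max_seqs,
        "max_gap_fraction": 0.66, "divergence_fraction": divergence_fraction})
    selected = select_orthogroups(groups, required_units, min_seqs, max_seqs,
                                  report=report)
    cleaned = []
    for i, og in enumerate(selected):
        out = filter_orthogroup(og, required_units, seed=seed + i, report=report)
        if out is not None:
            cleaned.append(out)
    final = filter_top_divergent(cleaned, divergence_fraction, min_seqs,
                                 report=report)
    return final, report
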