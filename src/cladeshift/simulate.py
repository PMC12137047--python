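"""Clade-structured tree and codon-alignment simulation.

The generator emulates the study design the analysis targets: a small number
of higher-taxon units (default four, 6+5+5+5 tips, 21 in total) arranged on a
ladder backbone, with branch lengths in expected substitutions per codon, and
codon alignments evolved under any of the four site / branch-site models.
Because only endpoint states matter under a continuous-time Markov chain,
evolution is simulated by exact sampling from the class-specific transition
matrices at branch granularity.  Everything is a pure function of its inputs
and the seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import (
    CodonAlignment,
    CodonFrequencies,
    build_rate_matrix,
    f3x4_frequencies,
    substitution_flux,
)
from .compare import select_best
from .filtering import Orthogroup
from .models import (
    CodonModelSpec,
    fit_all_models,
    mixture_layout,
)
from .trees import BranchLabeling, PhyloTree, UnitPartition, label_branches, parse_newick

#: Position-specific nucleotide frequencies (A, C, G, T at codon positions
#: 1..3) used as the default F3X4 regime: AT-rich third positions, the
#: composition typical of holometabolan insect coding sequence.
DEFAULT_POSITION_FREQS = np.array([
    [0.29, 0.19, 0.31, 0.21],
    [0.31, 0.22, 0.17, 0.30],
    [0.33, 0.17, 0.15, 0.35],
])

DEFAULT_UNIT_NAMES = ("H", "C", "L", "D")


def default_frequencies() -> CodonFrequencies:
    return f3x4_frequencies(DEFAULT_POSITION_FREQS)


@dataclass
class SimulationSpec:
    """Tree + model regime for one simulation.

    Lengths are in expected substitutions per codon.  Defaults give a 21-tip
    four-unit ladder whose maximum patristic path is a few substitutions per
    codon — deep enough for clear among-unit signal without saturation.
    """

    n_units: int = 4
    tips_per_unit: tuple[int, ...] | int = (6, 5, 5, 5)
    stem_length: float = 0.4
    within_depth: float = 0.4
    among_depth: float = 0.25
    jitter: float = 0.25  # lognormal sd applied to every branch length
    n_codons: int = 2000
    seed: int = 0
    unit_names: tuple[str, ...] | None = None

    def resolved_tips(self) -> tuple[int, ...]:
        if isinstance(self.tips_per_unit, int):
            return (self.tips_per_unit,) * self.n_units
        if len(self.tips_per_unit) != self.n_units:
            raise ValueError("tips_per_unit length must equal n_units")
        return tuple(self.tips_per_unit)

    def resolved_names(self) -> tuple[str, ...]:
        if self.unit_names is not None:
            return self.unit_names
        if self.n_units == 4:
            return DEFAULT_UNIT_NAMES
        return tuple(f"U{i + 1}" for i in range(self.n_units))


def _random_crown(tips: list[str], depth: float, rng: np.random.Generator) -> str:
    """Random-topology crown with tips at height 0 and the root at ``depth``."""
    if len(tips) == 1:
        return f"{tips[0]}:{depth:.10g}"
    k = len(tips)
    heights = np.sort(rng.uniform(0.15 * depth, depth, size=k - 1))
    heights[-1] = depth
    nodes = [(t, 0.0) for t in tips]
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (sa, ha), (sb, hb) = nodes[i], nodes[j]
        merged = (f"({sa}:{max(h - ha, 0):.10g},{sb}:{max(h - hb, 0):.10g})", h)
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0][0]


def simulate_units_tree(spec: SimulationSpec) -> tuple[PhyloTree, UnitPartition]:
    """Simulate the clade-structured species tree and its unit partition.

    Units sit on a ladder (the first unit sister to all the rest, matching a
    four-order topology (U1,(U2,(U3,U4)))); each unit is monophyletic with a
    random internal topology.  Branch lengths get multiplicative lognormal
    jitter with unit mean.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.resolved_names()
    sizes = spec.resolved_tips()
    crowns = []
    assignment: dict[str, str] = {}
    for unit, size in zip(names, sizes):
        tips = [f"{unit}{i + 1}" for i in range(size)]
        for t in tips:
            assignment[t] = unit
        crowns.append(_random_crown(tips, spec.within_depth, rng))
    stem = spec.stem_length
    nwk = f"{crowns[-1]}:{stem:.10g}"
    for crown in crowns[-2::-1]:
        nwk = f"({crown}:{stem:.10g},{nwk}):{spec.among_depth:.10g}"
    nwk = nwk.rsplit(":", 1)[0] + ";"  # root owns no branch
    tree = parse_newick(nwk)
    if spec.jitter > 0:
        sd = spec.jitter
        factors = np.exp(rng.normal(-0.5 * sd * sd, sd, size=tree.n_nodes))
        lengths = tree.lengths * factors
        lengths[tree.root] = np.nan
        tree = tree.with_lengths(lengths)
    return tree, UnitPartition(assignment, units=list(names))


@dataclass
class SimulatedAlignment:
    """A simulated codon alignment with its generating truth."""

    alignment: CodonAlignment
    class_index: np.ndarray          # per-codon mixture class index
    class_labels: list[str]
    tree: PhyloTree
    labeling: BranchLabeling
    truth: CodonModelSpec
    freqs: CodonFrequencies
    seed: int

    def true_class(self, codon: int) -> str:
        return self.class_labels[self.class_index[codon]]


def simulate_codon_alignment(tree: PhyloTree, labeling: BranchLabeling | None,
                             truth: CodonModelSpec, n_codons: int, seed: int,
                             freqs: CodonFrequencies | None = None) -> SimulatedAlignment:
    """Evolve a codon alignment down a labeled tree under a model's truth.

    Per codon a mixture class is drawn, the root codon is drawn from the
    stationary frequencies, and each branch applies that class's transition
    matrix with the branch's background or foreground omega.  Stop codons can
    never arise because the rate matrix excludes them.
    """
    freqs = freqs or default_frequencies()
    labeling = labeling or BranchLabeling.all_background(tree)
    tree._require_lengths()
    rng = np.random.default_rng(seed)
    mix = mixture_layout(truth)
    rho = float(sum(p * substitution_flux(freqs, truth.kappa, w)[0]
                    for p, w in zip(mix.proportions, mix.omega_bg)))
    class_index = rng.choice(mix.n_classes, size=n_codons, p=mix.proportions)
    nstate = freqs.code.n_sense
    states = np.empty((tree.n_nodes, n_codons), dtype=np.int32)
    states[tree.root] = rng.choice(nstate, size=n_codons, p=freqs.pi)
    qcache: dict[float, object] = {}

    def Q_of(omega: float):
        if omega not in qcache:
            qcache[omega] = build_rate_matrix(freqs, truth.kappa, float(omega))
        return qcache[omega]

    fg = labeling.foreground
    for v in range(tree.n_nodes - 2, -1, -1):  # preorder below the root
        parent_states = states[tree.parent[v]]
        t = tree.lengths[v] / rho
        for k in range(mix.n_classes):
            sites = np.where(class_index == k)[0]
            if sites.size == 0:
                continue
            omega = mix.omega_fg[k] if fg[v] else mix.omega_bg[k]
            P = Q_of(float(omega)).transition_matrix(t)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(sites.size)
            states[v, sites] = np.argmax(cum[parent_states[sites]] > u[:, None],
                                         axis=1)
    sense = freqs.code.sense_codons
    names, seqs = [], []
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            names.append(tree.tip_name[v])
            seqs.append("".join(sense[s] for s in states[v]))
    order = np.argsort(names)
    aln = CodonAlignment([names[i] for i in order], [seqs[i] for i in order],
                         code=freqs.code)
    return SimulatedAlignment(aln, class_index, list(mix.labels), tree,
                              labeling, truth, freqs, seed)


def simulate_study(spec: SimulationSpec, truth: CodonModelSpec,
                   freqs: CodonFrequencies | None = None
                   ) -> tuple[SimulatedAlignment, UnitPartition]:
    """Tree + partition + alignment in one call (seeds derived from spec.seed)."""
    tree, partition = simulate_units_tree(spec)
    labeling = label_branches(tree, partition)
    sim = simulate_codon_alignment(tree, labeling, truth, spec.n_codons,
                                   seed=spec.seed + 1, freqs=freqs)
    return sim, partition


# ---------------------------------------------------------------------------
# Reference simulate-and-refit experiment
# ---------------------------------------------------------------------------

#: Branch-site nearly-neutral estimates reported for the concatenated insect
#: alignment; used as generating truth in the recovery experiment.  The
#: transition/transversion ratio is not part of the published mixture
#: estimates; 2.5 is a typical value for insect nuclear coding sequence.
F3X4_REFERENCE_TRUTH = CodonModelSpec(
    3, kappa=2.5, omega0=0.040, p0=0.730, p1=0.043, scheme="F3X4")
FCODON_REFERENCE_TRUTH = CodonModelSpec(
    3, kappa=2.5, omega0=0.035, p0=0.708, p1=0.040, scheme="Fcodon")


def recovery_experiment(scheme: str = "F3X4", seed: int = 0,
                        n_codons: int = 2000, n_starts: int = 2,
                        truth: CodonModelSpec | None = None) -> dict:
    """Simulate under the branch-site nearly-neutral reference truth on a
    21-tip four-unit tree and refit models 1 and 3 with shared nuisance
    parameters; report the AIC comparison and the recovered class parameters.
    """
    if truth is None:
        truth = (F3X4_REFERENCE_TRUTH if scheme == "F3X4"
                 else FCODON_REFERENCE_TRUTH)
    spec = SimulationSpec(n_codons=n_codons, seed=seed)
    sim, _ = simulate_study(spec, truth, freqs=default_frequencies())
    fits = fit_all_models(sim.alignment, sim.tree, sim.labeling,
                          scheme=scheme, model_ids=(1, 3),
                          n_starts=n_starts, seed=seed + 17)
    comp = select_best(fits)
    mix = fits[3].mixture
    p = dict(zip(mix.labels, (float(x) for x in mix.proportions)))
    return {
        "scheme": scheme,
        "weight_model3": float(comp.weight(3)),
        "weight_model1": float(comp.weight(1)),
        "best_model": int(comp.best_model),
        "p0_hat": p["0"], "p1_hat": p["1"], "p2a_hat": p["2a"],
        "p2b_hat": p["2b"],
        "omega0_hat": float(fits[3].spec.omega0),
        "logL_model1": float(fits[1].log_likelihood),
        "logL_model3": float(fits[3].log_likelihood),
        "n_codons": n_codons, "n_tips": sim.tree.n_tips,
        "truth": {"p0": truth.p0, "p1": truth.p1, "omega0": truth.omega0},
    }


# ---------------------------------------------------------------------------
# Fixture doctoring for the filtering cascade
# ---------------------------------------------------------------------------

def _graft_sister(tree: PhyloTree, tip: str, new_name: str,
                  new_length: float = 0.01) -> PhyloTree:
    """Attach ``new_name`` as a zero-distance sister of ``tip``."""
    nwk = tree.to_newick()
    pattern = re.compile(r"(?<=[(,])" + re.escape(tip) + r":([0-9.eE+-]+)")
    m = pattern.search(nwk)
    if not m:
        raise ValueError(f"tip {tip!r} not found in Newick output")
    old_len = float(m.group(1))
    repl = (f"({tip}:{new_length:.10g},{new_name}:{new_length:.10g})"
            f":{max(old_len - new_length, 0):.10g}")
    return parse_newick(nwk[:m.start()] + repl + nwk[m.end():])


def inject_paralogs_and_outliers(og: Orthogroup, dup_rate: float = 0.0,
                                 outlier_scale: float | None = None,
                                 seed: int = 0,
                                 ancient_duplication: bool = False
                                 ) -> tuple[Orthogroup, dict]:
    """Doctor an orthogroup with known artefacts for filter testing.

    ``dup_rate``: per-species probability of adding a within-species duplicate
    leaf; ``outlier_scale``: multiply one random tip branch by this factor;
    ``ancient_duplication``: mirror the whole orthogroup into two sister
    all-unit clades.  Returns the doctored orthogroup and a ground-truth dict
    of what a correct filter should remove.
    """
    rng = np.random.default_rng(seed)
    truth: dict = {"duplicates": [], "outlier": None, "ancient_copy": []}
    tree, aln = og.tree, og.alignment
    species = dict(og.species)
    units = dict(og.units)

    if ancient_duplication:
        nwk = tree.to_newick().rstrip(";")
        copy = re.sub(r"(?<=[(,])([A-Za-z0-9_.|]+):",
                      lambda m: m.group(1) + "__anc:", nwk)
        tree = parse_newick(f"({nwk}:0.5,{copy}:0.5);")
        names = list(aln.names) + [f"{n}__anc" for n in aln.names]
        seqs = list(aln.seqs) * 2
        aln = CodonAlignment(names, seqs, code=aln.code)
        for n in og.alignment.names:
            species[f"{n}__anc"] = og.species[n]
            units[f"{n}__anc"] = og.units[n]
            truth["ancient_copy"].append(f"{n}__anc")

    if dup_rate > 0:
        for name in list(og.alignment.names):
            if rng.random() < dup_rate:
                dup = f"{name}__dup"
                tree = _graft_sister(tree, name, dup)
                aln = CodonAlignment(aln.names + [dup],
                                     aln.seqs + [aln.sequence(name)],
                                     code=aln.code)
                species[dup] = species[name]
                units[dup] = units[name]
                truth["duplicates"].append(dup)

    if outlier_scale is not None:
        tips = sorted(t for t in tree.tip_name.values())
        victim = tips[int(rng.integers(len(tips)))]
        node = next(v for v, n in tree.tip_name.items() if n == victim)
        lengths = tree.lengths.copy()
        lengths[node] *= outlier_scale
        tree = tree.with_lengths(lengths)
        truth["outlier"] = victim

    return Orthogroup(og.id, aln, tree, species, units), truth


# ---------------------------------------------------------------------------
# Saturation experiment
# ---------------------------------------------------------------------------

def saturation_experiment(truth: CodonModelSpec, depth_grid: list[float],
                          n_reps: int = 20, n_codons: int = 500, seed: int = 0,
                          spec: SimulationSpec | None = None,
                          freqs: CodonFrequencies | None = None,
                          n_starts: int = 2) -> pd.DataFrame:
    """Fit models 1 and 3 to data simulated under the site model across a
    depth grid, recording the false-preference rate for the branch-site model
    and the inflation of the estimated class-2a proportion.

    ``truth`` must be a site model (no among-unit shift); ``depth_grid``
    multiplies all branch lengths of the base simulated tree.
    """
    if truth.model_id not in (1, 2):
        raise ValueError("saturation experiment requires a site-model truth")
    base = spec or SimulationSpec()
    freqs = freqs or default_frequencies()
    rows = []
    for d_i, depth in enumerate(depth_grid):
        prefer3 = 0
        p2a_hats = []
        for rep in range(n_reps):
            rep_seed = seed + 1000 * d_i + rep
            tree, partition = simulate_units_tree(
                SimulationSpec(**{**base.__dict__, "seed": rep_seed}))
            tree = tree.with_lengths(tree.lengths * depth)
            labeling = label_branches(tree, partition)
            sim = simulate_codon_alignment(tree, labeling, truth, n_codons,
                                           seed=rep_seed + 7, freqs=freqs)
            fits = fit_all_models(sim.alignment, tree, labeling,
                                  scheme=truth.scheme, model_ids=(1, 3),
                                  n_starts=n_starts, seed=rep_seed)
            comp = select_best(fits)
            if comp.best_model == 3:
                prefer3 += 1
            m3 = fits[3].mixture
            p2a_hats.append(float(m3.proportions[m3.labels.index("2a")]))
        rows.append({
            "depth": depth,
            "fraction_prefer_branch_site": prefer3 / n_reps,
            "mean_p2a_hat": float(np.mean(p2a_hats)),
            "mean_p2a_bias": float(np.mean(p2a_hats)),  # truth p2a = 0
            "n_reps": n_reps, "n_codons": n_codons,
        })
    return pd.DataFrame(rows)
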