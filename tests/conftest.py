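import numpy as np
import pytest

from cladeshift.codon import build_rate_matrix, substitution_flux
from cladeshift.models import CodonModelSpec, FitResult, mixture_layout
from cladeshift.trees import (
    BranchLabeling,
    UnitPartition,
    label_branches,
    parse_newick,
)
from cladeshift.simulate import default_frequencies, simulate_codon_alignment


@pytest.fixture(scope="session")
def freqs():
    return default_frequencies()


@pytest.fixture(scope="session")
def quartet():
    """4-tip labeled tree with two 2-tip units."""
    tree = parse_newick("((a:0.3,b:0.5):0.2,(c:0.4,d:0.1):0.3);")
    partition = UnitPartition({"a": "A", "b": "A", "c": "B", "d": "B"})
    return tree, partition, label_branches(tree, partition)


@pytest.fixture(scope="session")
def quartet_sim(quartet, freqs):
    tree, _, labeling = quartet
    truth = CodonModelSpec(3, kappa=2.5, omega0=0.05, p0=0.6, p1=0.1)
    return simulate_codon_alignment(tree, labeling, truth, 40, seed=7,
                                    freqs=freqs)


def ladder(names, bl=0.2):
    s = f"({names[0]}:{bl},{names[1]}:{bl})"
    for nm in names[2:]:
        s = f"({s}:{bl},{nm}:{bl})"
    return s


@pytest.fixture(scope="session")
def insect_tree():
    """21-tip tree shaped like the four-order study system: sizes 6,5,5,5,
    topology (H,(C,(L,D)))."""
    H = ladder([f"H{i}" for i in range(5)])
    C = ladder([f"C{i}" for i in range(6)])
    L = ladder([f"L{i}" for i in range(5)])
    D = ladder([f"D{i}" for i in range(5)])
    nwk = f"({H}:0.3,({C}:0.3,({L}:0.3,{D}:0.3):0.2):0.2);"
    tree = parse_newick(nwk)
    partition = UnitPartition(
        {t: t[0] for t in tree.tip_name.values()}, units=["H", "C", "L", "D"])
    return tree, partition


def brute_force_loglik(aln, tree, labeling, spec, freqs):
    """Independent likelihood oracle: explicit marginalization over all
    internal-state assignments (feasible for <=4 tips)."""
    mix = mixture_layout(spec)
    rho = sum(p * substitution_flux(freqs, spec.kappa, w)[0]
              for p, w in zip(mix.proportions, mix.omega_bg))
    mat = aln.codon_matrix()
    row = {v: aln.names.index(tree.tip_name[v])
           for v in range(tree.n_nodes) if tree.is_tip(v)}
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    n = freqs.code.n_sense
    out = np.zeros(aln.n_codons)
    Ps_by_class = []
    for k in range(mix.n_classes):
        Ps = {}
        for v in tree.branches():
            om = mix.omega_fg[k] if labeling.foreground[v] else mix.omega_bg[k]
            Q = build_rate_matrix(freqs, spec.kappa, float(om))
            Ps[v] = Q.transition_matrix(tree.lengths[v] / rho)
        Ps_by_class.append(Ps)
    grids = np.meshgrid(*[np.arange(n)] * len(internals), indexing="ij")
    assign = {v: g.ravel() for v, g in zip(internals, grids)}
    for s in range(aln.n_codons):
        site = 0.0
        for k in range(mix.n_classes):
            Ps = Ps_by_class[k]
            prob = freqs.pi[assign[tree.root]].copy()
            for v in tree.branches():
                pv = assign[tree.parent[v]]
                sv = assign[v] if v in assign else np.full(pv.shape,
                                                           mat[row[v], s])
                prob *= Ps[v][pv, sv]
            site += mix.proportions[k] * prob.sum()
        out[s] = np.log(site)
    return out


def make_fit(model_id, logL, *, omega2=None, omega0=0.05, p0=0.7, p1=0.1,
             data_hash="fixture", tree=None, labeling=None, freqs=None):
    """Minimal FitResult for model-selection tests (no likelihood machinery)."""
    kwargs = {}
    if model_id != 1:
        kwargs["p1"] = p1
    if model_id in (2, 4):
        kwargs["omega2"] = omega2 if omega2 is not None else 2.0
    spec = CodonModelSpec(model_id, kappa=2.0, omega0=omega0, p0=p0, **kwargs)
    if tree is None:
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    if labeling is None:
        labeling = BranchLabeling.all_background(tree)
    return FitResult(
        spec=spec, mixture=mixture_layout(spec), log_likelihood=logL,
        site_loglik=np.array([]), kappa=2.0, branch_scale=1.0, tree=tree,
        labeling=labeling, freqs=freqs, data_hash=data_hash)
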