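"""Site and branch-site codon models: likelihoods, ML fitting, site posteriors.

Four models are supported, numbered as in the comparison they serve:

1. *site nearly-neutral*: two site classes, purifying (omega0 < 1) and
   neutral (omega1 = 1); free parameters p0, omega0.
2. *site positive-selection*: adds an adaptive class with omega2 >= 1; free
   parameters p0, p1, omega0, omega2.
3. *branch-site nearly-neutral*: classes 0 and 1 as in model 1 plus classes
   2a/2b whose codons are purifying/neutral on background (within-unit)
   branches but evolve with omega2 fixed at 1 on foreground (among-unit)
   branches; free parameters p0, p1, omega0.
4. *branch-site positive-selection*: as model 3 but omega2 >= 1 is free.

The 2a/2b proportions follow the constrained expansion
``p2a = (1-p0-p1) * p0/(p0+p1)`` and ``p2b = (1-p0-p1) * p1/(p0+p1)``, so the
free-parameter counts are 2/4/3/4 and models 2 and 4 have equal complexity.

Likelihoods use Felsenstein pruning over the 61 sense codons with site-pattern
compression and per-node log scaling.  Rate matrices share one scale factor
per model so that the background-mixture expected substitution rate is 1,
i.e. branch lengths are expected substitutions per codon.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .codon import (
    Alignment,
    CodonAlignment,
    CodonFrequencies,
    CodonRateMatrix,
    build_rate_matrix,
    estimate_frequencies,
    substitution_flux,
)
from .trees import BranchLabeling, PhyloTree, patristic_matrix

logger = logging.getLogger("cladeshift")

MODEL_IDS = (1, 2, 3, 4)
MODEL_NAMES = {1: "site nearly-neutral", 2: "site positive-selection",
               3: "branch-site nearly-neutral", 4: "branch-site positive-selection"}


# ---------------------------------------------------------------------------
# Model specification and mixture layout
# ---------------------------------------------------------------------------

@dataclass
class CodonModelSpec:
    """Parameter values of one of the four codon models."""

    model_id: int
    kappa: float = 2.0
    omega0: float = 0.1
    p0: float = 0.8
    p1: float | None = None     # model 1: implicitly 1 - p0
    omega2: float | None = None  # models 2/4 free; model 3 fixed at 1
    scheme: str = "F3X4"

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id}")
        if self.model_id == 1:
            self.p1 = None if self.p1 is None else self.p1
            self.omega2 = None
        else:
            if self.p1 is None:
                raise ValueError(f"model {self.model_id} requires p1")
        if self.model_id == 3:
            self.omega2 = 1.0
        if self.model_id in (2, 4) and self.omega2 is None:
            raise ValueError(f"model {self.model_id} requires omega2")

    @property
    def n_free_parameters(self) -> int:
        return {1: 2, 2: 4, 3: 3, 4: 4}[self.model_id]

    @property
    def is_branch_site(self) -> bool:
        return self.model_id in (3, 4)


@dataclass
class SiteClassMixture:
    """Per-class (label, proportion, background omega, foreground omega)."""

    labels: list[str]
    proportions: np.ndarray
    omega_bg: np.ndarray
    omega_fg: np.ndarray

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.omega_bg = np.asarray(self.omega_bg, dtype=float)
        self.omega_fg = np.asarray(self.omega_fg, dtype=float)
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-9):
            raise ValueError("class proportions must sum to 1")
        if np.any(self.proportions < -1e-12):
            raise ValueError("negative class proportion")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def as_rows(self) -> list[tuple[str, float, float, float]]:
        return [
            (lb, float(p), float(wb), float(wf))
            for lb, p, wb, wf in zip(self.labels, self.proportions,
                                     self.omega_bg, self.omega_fg)
        ]


def mixture_layout(spec: CodonModelSpec) -> SiteClassMixture:
    """Expand a model spec into its site-class mixture."""
    w0, k = spec.omega0, spec.model_id
    if not (0 <= spec.p0 <= 1):
        raise ValueError(f"p0 out of [0,1]: {spec.p0}")
    if k == 1:
        return SiteClassMixture(["0", "1"], [spec.p0, 1 - spec.p0],
                                [w0, 1.0], [w0, 1.0])
    p0, p1 = spec.p0, spec.p1
    if p1 < 0 or p0 + p1 > 1 + 1e-12:
        raise ValueError(f"invalid proportions p0={p0}, p1={p1}")
    if k == 2:
        return SiteClassMixture(["0", "1", "2"], [p0, p1, 1 - p0 - p1],
                                [w0, 1.0, spec.omega2], [w0, 1.0, spec.omega2])
    w2 = 1.0 if k == 3 else spec.omega2
    rest = max(1 - p0 - p1, 0.0)
    if p0 + p1 <= 0:
        raise ValueError("p0 + p1 must be positive for branch-site models")
    p2a = rest * p0 / (p0 + p1)
    p2b = rest * p1 / (p0 + p1)
    return SiteClassMixture(
        ["0", "1", "2a", "2b"], [p0, p1, p2a, p2b],
        [w0, 1.0, w0, 1.0], [w0, 1.0, w2, w2],
    )


# ---------------------------------------------------------------------------
# Likelihood engine (pruning over sense codons)
# ---------------------------------------------------------------------------

class CodonLikelihood:
    """Pruning likelihood for one (alignment, tree, labeling) triple.

    Site patterns are compressed once; each call evaluates per-class per-site
    log-likelihoods for a mixture at given kappa and branch-length scale.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree,
                 labeling: BranchLabeling | None,
                 freqs: CodonFrequencies):
        if set(tree.tip_name.values()) != set(aln.names):
            raise ValueError("alignment names and tree tips do not match")
        tree._require_lengths()
        self.aln = aln
        self.tree = tree
        self.labeling = labeling or BranchLabeling.all_background(tree)
        self.freqs = freqs
        self.code = aln.code
        mat = aln.codon_matrix()
        cols, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True)
        self.patterns = cols           # (n_seqs, n_patterns)
        self.pattern_of_site = inverse.ravel()
        self.pattern_counts = counts.astype(float)
        self.n_sites = aln.n_codons
        self.n_patterns = cols.shape[1]
        row_of = {n: i for i, n in enumerate(aln.names)}
        self.tip_row = {v: row_of[tree.tip_name[v]]
                        for v in range(tree.n_nodes) if tree.is_tip(v)}
        self.data_hash = hashlib.sha256(
            ("".join(aln.names) + "".join(aln.seqs)).encode()).hexdigest()[:16]
        self._qcache: dict[tuple[float, float], CodonRateMatrix] = {}

    def _rate_matrix(self, kappa: float, omega: float) -> CodonRateMatrix:
        key = (round(kappa, 12), round(omega, 12))
        if key not in self._qcache:
            if len(self._qcache) > 64:
                self._qcache.clear()
            self._qcache[key] = build_rate_matrix(self.freqs, kappa, omega)
        return self._qcache[key]

    def mixture_scale(self, mixture: SiteClassMixture, kappa: float) -> float:
        """Background-mixture expected substitution rate of the unscaled Q's."""
        return float(sum(
            p * substitution_flux(self.freqs, kappa, w)[0]
            for p, w in zip(mixture.proportions, mixture.omega_bg)))

    def class_site_loglik(self, mixture: SiteClassMixture, kappa: float,
                          scale: float = 1.0) -> np.ndarray:
        """(n_classes, n_patterns) per-class per-pattern log-likelihoods."""
        tree, fg = self.tree, self.labeling.foreground
        rho = self.mixture_scale(mixture, kappa)
        out = np.empty((mixture.n_classes, self.n_patterns))
        done: dict[tuple[float, float], int] = {}
        for k in range(mixture.n_classes):
            key = (round(float(mixture.omega_bg[k]), 14),
                   round(float(mixture.omega_fg[k]), 14))
            if key in done:
                out[k] = out[done[key]]
                continue
            done[key] = k
            Ps = {}
            for v in tree.branches():
                omega = mixture.omega_fg[k] if fg[v] else mixture.omega_bg[k]
                Q = self._rate_matrix(kappa, float(omega))
                Ps[v] = Q.transition_matrix(tree.lengths[v] * scale / rho)
            out[k] = self._prune(Ps)
        return out

    def _prune(self, Ps: dict[int, np.ndarray]) -> np.ndarray:
        tree = self.tree
        npat, nstate = self.n_patterns, self.code.n_sense
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for v in range(tree.n_nodes):
            if tree.is_tip(v):
                continue
            L = np.ones((npat, nstate))
            for c in tree.children[v]:
                if tree.is_tip(c):
                    codes = self.patterns[self.tip_row[c]]
                    L *= Ps[c][:, codes].T
                else:
                    L *= partial.pop(c) @ Ps[c].T
            m = L.max(axis=1)
            m[m == 0] = 1.0
            L /= m[:, None]
            logscale += np.log(m)
            partial[v] = L
        root_lik = partial[tree.root] @ self.freqs.pi
        with np.errstate(divide="ignore"):
            return np.log(root_lik) + logscale

    def site_loglik(self, mixture: SiteClassMixture, kappa: float,
                    scale: float = 1.0) -> tuple[float, np.ndarray]:
        """(total logL, per-codon log-likelihood vector)."""
        cls = self.class_site_loglik(mixture, kappa, scale)
        with np.errstate(divide="ignore"):
            logw = np.log(mixture.proportions)[:, None]
        per_pattern = logsumexp(cls + logw, axis=0)
        total = float(per_pattern @ self.pattern_counts)
        return total, per_pattern[self.pattern_of_site]


def log_likelihood(aln: CodonAlignment, tree: PhyloTree,
                   labeling: BranchLabeling | None, spec: CodonModelSpec,
                   freqs: CodonFrequencies | None = None,
                   scale: float = 1.0) -> tuple[float, np.ndarray]:
    """Total and per-codon log-likelihood of a model on a labeled tree."""
    freqs = freqs or estimate_frequencies(aln, spec.scheme)
    engine = CodonLikelihood(aln, tree, labeling, freqs)
    return engine.site_loglik(mixture_layout(spec), spec.kappa, scale)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """MLEs, likelihood and diagnostics of one model fit."""

    spec: CodonModelSpec
    mixture: SiteClassMixture
    log_likelihood: float
    site_loglik: np.ndarray
    kappa: float
    branch_scale: float
    tree: PhyloTree                       # lengths as used (scaled)
    labeling: BranchLabeling
    freqs: CodonFrequencies
    data_hash: str
    n_starts: int = 1
    start_loglik: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    class_site_loglik: np.ndarray | None = None   # (classes, patterns)
    pattern_of_site: np.ndarray | None = None

    @property
    def model_id(self) -> int:
        return self.spec.model_id

    @property
    def n_free_parameters(self) -> int:
        return self.spec.n_free_parameters

    def summary(self) -> dict:
        mix = {f"p{lb}": p for lb, p, _, _ in self.mixture.as_rows()}
        return {
            "model": self.model_id,
            "type": MODEL_NAMES[self.model_id],
            **mix,
            "w0": self.spec.omega0,
            "w1": 1.0,
            "w2": self.spec.omega2,
            "kappa": self.kappa,
            "logL": self.log_likelihood,
        }


def _pack_start(model_id: int, rng: np.random.Generator, which: int,
                opt_kappa: bool, opt_scale: bool) -> np.ndarray:
    """Starting point in the unconstrained parameter space."""
    if which == 0:
        p0, p1, w0, w2 = 0.7, 0.15, 0.1, 1.5
        kap, sc = 2.0, 1.0
    elif which == 1:
        p0, p1, w0, w2 = 0.5, 0.25, 0.3, 5.0
        kap, sc = 3.0, 1.0
    else:
        p0 = rng.uniform(0.2, 0.9)
        p1 = rng.uniform(0.05, 0.95) * (1 - p0)
        w0 = rng.uniform(0.01, 0.9)
        w2 = 1.0 + rng.exponential(2.0)
        kap = rng.uniform(1.0, 5.0)
        sc = np.exp(rng.normal(0, 0.3))
    x = []
    if opt_kappa:
        x.append(np.log(kap))
    if opt_scale:
        x.append(np.log(sc))
    if model_id == 1:
        x += [logit(p0), logit(w0)]
    else:
        rest = max(1 - p0 - p1, 1e-3)
        x += [np.log(p0 / rest), np.log(p1 / rest), logit(w0)]
        if model_id in (2, 4):
            x.append(np.log(w2 - 1 + 1e-6))
    return np.array(x)


def _unpack(x: np.ndarray, model_id: int, scheme: str,
            opt_kappa: bool, opt_scale: bool,
            kappa0: float, scale0: float) -> tuple[CodonModelSpec, float]:
    i = 0
    kappa, scale = kappa0, scale0
    if opt_kappa:
        kappa = float(np.exp(np.clip(x[i], -5, 5))); i += 1
    if opt_scale:
        scale = float(np.exp(np.clip(x[i], -8, 8))); i += 1
    if model_id == 1:
        p0 = float(expit(x[i])); w0 = float(expit(x[i + 1]))
        spec = CodonModelSpec(1, kappa=kappa, omega0=w0, p0=p0, scheme=scheme)
        return spec, scale
    a0, a1 = x[i], x[i + 1]
    w0 = float(expit(x[i + 2]))
    z = np.array([a0, a1, 0.0])
    z -= z.max()
    e = np.exp(z)
    p = e / e.sum()
    omega2 = None
    if model_id in (2, 4):
        omega2 = 1.0 + float(np.exp(np.clip(x[i + 3], -25, 6)))
    spec = CodonModelSpec(model_id, kappa=kappa, omega0=w0,
                          p0=float(p[0]), p1=float(p[1]), omega2=omega2,
                          scheme=scheme)
    return spec, scale


def fit_model(aln: CodonAlignment, tree: PhyloTree,
              labeling: BranchLabeling | None, model_id: int, *,
              scheme: str = "F3X4", freqs: CodonFrequencies | None = None,
              kappa: float | None = None, optimize_scale: bool = True,
              n_starts: int = 3, seed: int = 0,
              engine: CodonLikelihood | None = None) -> FitResult:
    """Fit one codon model by maximum likelihood.

    Parameters are optimized in an unconstrained transform (log kappa, logit
    omega0, log(omega2-1), softmax proportions, log branch-length scale) with
    L-BFGS-B from ``n_starts`` starting points; the best start is kept.  With
    ``kappa`` given and ``optimize_scale=False`` only the class parameters are
    free — the shared-nuisance protocol in which kappa and branch lengths come
    from a single model-1 fit.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id}")
    freqs = freqs or estimate_frequencies(aln, scheme)
    eng = engine or CodonLikelihood(aln, tree, labeling, freqs)
    opt_kappa = kappa is None
    kappa0 = 2.0 if opt_kappa else float(kappa)
    rng = np.random.default_rng(seed)
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        spec, scale = _unpack(x, model_id, scheme, opt_kappa, optimize_scale,
                              kappa0, 1.0)
        mix = mixture_layout(spec)
        cls = eng.class_site_loglik(mix, spec.kappa, scale)
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(mix.proportions, 1e-300))[:, None]
        per_pattern = logsumexp(cls + logw, axis=0)
        return -float(per_pattern @ eng.pattern_counts)

    best = None
    start_lls = []
    failures = []
    for s in range(n_starts):
        x0 = _pack_start(model_id, rng, s, opt_kappa, optimize_scale)
        try:
            res = minimize(objective, x0, method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-10,
                                    "gtol": 1e-6})
        except Exception as exc:  # pragma: no cover - optimizer blow-up
            failures.append(str(exc))
            continue
        start_lls.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {n_starts} optimizer starts failed for model {model_id}: "
            f"{failures}")
    spec, scale = _unpack(best.x, model_id, scheme, opt_kappa, optimize_scale,
                          kappa0, 1.0)
    if model_id in (2, 4):
        # boundary check: omega2 >= 1 puts the nearly-neutral solution on the
        # constraint boundary, where the log(omega2 - 1) transform converges
        # slowly; accept the boundary whenever it is not measurably worse
        bd_spec = replace(spec, omega2=1.0)
        bd_mix = mixture_layout(bd_spec)
        cls_b = eng.class_site_loglik(bd_mix, bd_spec.kappa, scale)
        with np.errstate(divide="ignore"):
            logw_b = np.log(np.maximum(bd_mix.proportions, 1e-300))[:, None]
        bd_ll = float(logsumexp(cls_b + logw_b, axis=0) @ eng.pattern_counts)
        if bd_ll >= -best.fun - 1e-4:
            spec = bd_spec
            best.fun = min(best.fun, -bd_ll)
    mix = mixture_layout(spec)
    cls = eng.class_site_loglik(mix, spec.kappa, scale)
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(mix.proportions, 1e-300))[:, None]
    per_pattern = logsumexp(cls + logw, axis=0)
    total = float(per_pattern @ eng.pattern_counts)
    return FitResult(
        spec=spec, mixture=mix, log_likelihood=total,
        site_loglik=per_pattern[eng.pattern_of_site],
        kappa=spec.kappa, branch_scale=scale,
        tree=tree.with_lengths(tree.lengths * scale),
        labeling=eng.labeling, freqs=freqs, data_hash=eng.data_hash,
        n_starts=n_starts, start_loglik=start_lls, n_evaluations=n_eval,
        class_site_loglik=cls, pattern_of_site=eng.pattern_of_site,
    )


def fit_all_models(aln: CodonAlignment, tree: PhyloTree,
                   labeling: BranchLabeling, *, scheme: str = "F3X4",
                   model_ids: tuple[int, ...] = (1, 2, 3, 4),
                   n_starts: int = 3, seed: int = 0,
                   reoptimize_nuisance: bool = False) -> dict[int, FitResult]:
    """Fit several models with shared nuisance parameters.

    Kappa and the branch-length scale are estimated once under model 1 and
    then fixed for the remaining models, so only the class parameters of the
    model comparison differ in dimension (the 2/4/3/4 free-parameter
    accounting).  ``reoptimize_nuisance=True`` re-estimates both per model.
    """
    freqs = estimate_frequencies(aln, scheme)
    engine = CodonLikelihood(aln, tree, labeling, freqs)
    fits: dict[int, FitResult] = {}
    m1 = fit_model(aln, tree, labeling, 1, scheme=scheme, freqs=freqs,
                   kappa=None, optimize_scale=True, n_starts=n_starts,
                   seed=seed, engine=engine)
    fits[1] = m1
    for mid in model_ids:
        if mid == 1:
            continue
        if reoptimize_nuisance:
            fits[mid] = fit_model(aln, tree, labeling, mid, scheme=scheme,
                                  freqs=freqs, kappa=None, optimize_scale=True,
                                  n_starts=n_starts, seed=seed + mid,
                                  engine=engine)
        else:
            scaled = tree.with_lengths(tree.lengths * m1.branch_scale)
            eng2 = CodonLikelihood(aln, scaled,
                                   BranchLabeling(scaled, labeling.foreground),
                                   freqs)
            fits[mid] = fit_model(aln, scaled,
                                  BranchLabeling(scaled, labeling.foreground),
                                  mid, scheme=scheme, freqs=freqs,
                                  kappa=m1.kappa, optimize_scale=False,
                                  n_starts=n_starts, seed=seed + mid,
                                  engine=eng2)
    return {mid: fits[mid] for mid in sorted(fits)}


# ---------------------------------------------------------------------------
# Empirical-Bayes site classification
# ---------------------------------------------------------------------------

@dataclass
class SiteClassification:
    """Per-codon posterior class membership (naive empirical Bayes at MLEs)."""

    labels: list[str]
    posterior: np.ndarray  # (n_sites, n_classes)
    threshold: float = 0.95

    def prob(self, label: str) -> np.ndarray:
        return self.posterior[:, self.labels.index(label)]

    def high_confidence(self, label: str = "2a") -> np.ndarray:
        """Boolean mask of codons with posterior(label) > threshold."""
        return self.prob(label) > self.threshold


def classify_sites(fit: FitResult, threshold: float = 0.95) -> SiteClassification:
    """Posterior class membership per codon at the fitted parameter values.

    This is the naive empirical-Bayes posterior
    ``p_k L_k(site) / sum_j p_j L_j(site)`` evaluated at the MLEs; parameter
    uncertainty is not integrated over.
    """
    if not fit.spec.is_branch_site:
        raise ValueError("site classification into 2a requires a branch-site fit")
    if fit.class_site_loglik is None:
        raise ValueError("fit carries no per-class site likelihoods")
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(fit.mixture.proportions, 1e-300))[:, None]
    lg = fit.class_site_loglik + logw
    lg -= logsumexp(lg, axis=0, keepdims=True)
    post = np.exp(lg).T[fit.pattern_of_site]
    return SiteClassification(list(fit.mixture.labels), post, threshold)


# ---------------------------------------------------------------------------
# dS-scaled branch lengths
# ---------------------------------------------------------------------------

def ds_scaled_tree(tree: PhyloTree, labeling: BranchLabeling,
                   mixture: SiteClassMixture, kappa: float,
                   freqs: CodonFrequencies) -> tuple[PhyloTree, float]:
    """Rescale branch lengths to synonymous substitutions per codon.

    Per branch, dS = t * (mixture synonymous flux fraction for the branch's
    label) / (proportion of synonymous sites from the omega=1 matrix), with
    sites counted by mutational opportunity (Goldman-Yang style).  Returns
    the rescaled tree and the maximum patristic pairwise dS between tips.
    """
    rho = float(sum(p * substitution_flux(freqs, kappa, w)[0]
                    for p, w in zip(mixture.proportions, mixture.omega_bg)))
    tot1, syn1 = substitution_flux(freqs, kappa, 1.0)
    prop_syn_sites = syn1 / tot1

    def syn_fraction(omegas: np.ndarray) -> float:
        syn = sum(p * substitution_flux(freqs, kappa, w)[1]
                  for p, w in zip(mixture.proportions, omegas))
        return float(syn) / rho

    frac_bg = syn_fraction(mixture.omega_bg)
    frac_fg = syn_fraction(mixture.omega_fg)
    fg = labeling.foreground
    ds = np.array([
        tree.lengths[v] * (frac_fg if fg[v] else frac_bg) / prop_syn_sites
        if v != tree.root else np.nan
        for v in range(tree.n_nodes)
    ])
    ds_tree = tree.with_lengths(ds)
    dmax = float(patristic_matrix(ds_tree).values.max())
    return ds_tree, dmax


def ds_branch_lengths(fit: FitResult) -> tuple[PhyloTree, float]:
    """dS-scaled tree and maximum patristic dS at a fit's parameter values."""
    return ds_scaled_tree(fit.tree, fit.labeling, fit.mixture, fit.kappa,
                          fit.freqs)


# ---------------------------------------------------------------------------
# Nucleotide GTR branch-length fitting
# ---------------------------------------------------------------------------

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _nt_patterns(aln: Alignment, tree: PhyloTree):
    """Integer-coded nucleotide columns; non-ACGT treated as missing (-1)."""
    mat = np.full((aln.n_seqs, aln.length), -1, dtype=np.int8)
    for i, s in enumerate(aln.seqs):
        for j, ch in enumerate(s):
            mat[i, j] = _NT_INDEX.get(ch, -1)
    cols, inv, counts = np.unique(mat, axis=1, return_inverse=True,
                                  return_counts=True)
    row_of = {n: i for i, n in enumerate(aln.names)}
    tip_row = {v: row_of[tree.tip_name[v]]
               for v in range(tree.n_nodes) if tree.is_tip(v)}
    return cols, counts.astype(float), tip_row


def _gtr_q(rates: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Normalized GTR rate matrix from 6 exchangeabilities (AC,AG,AT,CG,CT,GT)."""
    S = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    S[iu] = rates
    S += S.T
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def _gtr_loglik(lengths: np.ndarray, Q: np.ndarray, pi: np.ndarray,
                tree: PhyloTree, cols, counts, tip_row) -> float:
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    lam, U = np.linalg.eigh(0.5 * (B + B.T))
    right = (U.T / sq[None, :]).T
    left = U.T * sq[None, :]
    npat = cols.shape[1]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    eye_row = np.ones(4)
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            continue
        L = np.ones((npat, 4))
        for c in tree.children[v]:
            P = (right * np.exp(lam * lengths[c])) @ left
            np.clip(P, 0.0, None, out=P)
            if tree.is_tip(c):
                codes = cols[tip_row[c]]
                M = np.where(codes[:, None] >= 0,
                             P[:, np.clip(codes, 0, 3)].T, eye_row[None, :])
                L *= M
            else:
                L *= partial.pop(c) @ P.T
        m = L.max(axis=1)
        m[m == 0] = 1.0
        L /= m[:, None]
        logscale += np.log(m)
        partial[v] = L
    lik = partial[tree.root] @ pi
    with np.errstate(divide="ignore"):
        return float((np.log(lik) + logscale) @ counts)


def fit_gtr_branch_lengths(nt_aln: Alignment, topology: PhyloTree, *,
                           equal_rates: bool = False,
                           uniform_freqs: bool = False,
                           seed: int = 0) -> tuple[PhyloTree, dict]:
    """ML branch lengths on a fixed topology under a GTR nucleotide model.

    Base frequencies are empirical (or uniform); the six exchangeabilities are
    estimated jointly with the branch lengths unless ``equal_rates`` pins them
    (the Jukes-Cantor/F81 limit).  Returns the tree with fitted lengths plus a
    diagnostics dict (logL, exchangeabilities, frequencies).
    """
    if set(topology.tip_name.values()) != set(nt_aln.names):
        raise ValueError("alignment names and tree tips do not match")
    cols, counts, tip_row = _nt_patterns(nt_aln, topology)
    if uniform_freqs:
        pi = np.full(4, 0.25)
    else:
        flat = np.concatenate([cols[i] for i in range(cols.shape[0])])
        obs = np.bincount(flat[flat >= 0], minlength=4).astype(float)
        pi = np.maximum(obs, 1.0)
        pi /= pi.sum()
    branches = topology.branches()
    nb = len(branches)
    variable = cols.shape[1] > 1 or np.unique(cols[:, 0][cols[:, 0] >= 0]).size > 1
    if not variable:
        logger.warning("constant alignment: GTR branch lengths are ~0")
    x0 = np.concatenate([np.full(nb, np.log(0.05)),
                         [] if equal_rates else np.zeros(5)])

    def unpack(x):
        lens = np.zeros(topology.n_nodes)
        lens[branches] = np.exp(np.clip(x[:nb], -18, 4))
        if equal_rates:
            rates = np.ones(6)
        else:
            rates = np.concatenate([np.exp(np.clip(x[nb:], -8, 8)), [1.0]])
        return lens, rates

    def objective(x):
        lens, rates = unpack(x)
        return -_gtr_loglik(lens, _gtr_q(rates, pi), pi, topology,
                            cols, counts, tip_row)

    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7})
    lens, rates = unpack(res.x)
    fitted = topology.with_lengths(lens)
    info = {"log_likelihood": -float(res.fun), "exchangeabilities": rates,
            "frequencies": pi, "converged": bool(res.success)}
    return fitted, info
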