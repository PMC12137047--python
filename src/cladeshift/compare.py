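"""AIC model selection with the uninformative-parameter exclusion rule.

The four codon models are compared per dataset with
``AIC = -2 logL + 2k`` and Akaike weights ``exp(-deltaAIC/2)`` normalized over
the retained models.  Because the positive-selection models (2 and 4) nest
their nearly-neutral counterparts only through the boundary ``omega2 = 1``, a
fitted ``omega2`` indistinguishable from 1 is an uninformative parameter and
the richer model is excluded before the comparison.  Alternative
taxon-structure labelings (all with the same parameter count) are ranked the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import FitResult

#: |omega2_hat - 1| below this counts as "estimated as 1.0".
UNINFORMATIVE_TOL = 1e-3

_FREE_PARAMS = {1: 2, 2: 4, 3: 3, 4: 4}


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion, -2 logL + 2k."""
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    return -2.0 * log_likelihood + 2.0 * k


def count_free_parameters(model_id: int) -> int:
    """Free-parameter counts 2/4/3/4 for models 1-4 (class parameters only;
    nuisance parameters are shared across models)."""
    try:
        return _FREE_PARAMS[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id}") from None


def aic_weights(aics) -> np.ndarray:
    """Normalized Akaike weights exp(-deltaAIC/2) / sum."""
    a = np.asarray(list(aics), dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AIC value")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def relative_likelihoods(aics) -> np.ndarray:
    """Unnormalized exp(-deltaAIC/2)."""
    a = np.asarray(list(aics), dtype=float)
    return np.exp(-0.5 * (a - a.min()))


def detect_uninformative(fits: dict[int, FitResult],
                         tol: float = UNINFORMATIVE_TOL) -> list[int]:
    """Model ids (among 2 and 4) whose fitted omega2 collapses onto 1."""
    excluded = []
    for rich in (2, 4):
        if rich in fits:
            w2 = fits[rich].spec.omega2
            if w2 is not None and abs(w2 - 1.0) < tol:
                excluded.append(rich)
    return excluded


@dataclass
class ModelComparison:
    """Per-model AIC table with exclusions, weights and the winner."""

    table: pd.DataFrame  # index: model id / name
    best_model: int | str
    excluded: list = field(default_factory=list)

    def weight(self, model) -> float:
        return float(self.table.loc[model, "weight"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def select_best(fits: dict[int, FitResult],
                tol: float = UNINFORMATIVE_TOL) -> ModelComparison:
    """AIC comparison of fitted models with uninformative-parameter exclusion.

    Excluded models keep their logL/AIC in the table but carry zero weight;
    weights are normalized over the retained models.
    """
    if not fits:
        raise ValueError("no fits to compare")
    excluded = detect_uninformative(fits, tol)
    ids = sorted(fits)
    rows = []
    for mid in ids:
        f = fits[mid]
        k = count_free_parameters(mid)
        rows.append({"model": mid, "k": k, "logL": f.log_likelihood,
                     "AIC": aic(f.log_likelihood, k),
                     "excluded": mid in excluded,
                     "exclusion_reason": ("omega2 uninformative (=1)"
                                          if mid in excluded else "")})
    df = pd.DataFrame(rows).set_index("model")
    retained = df[~df["excluded"]]
    w = aic_weights(retained["AIC"])
    rel = relative_likelihoods(retained["AIC"])
    df["deltaAIC"] = np.nan
    df.loc[retained.index, "deltaAIC"] = retained["AIC"] - retained["AIC"].min()
    df["weight"] = 0.0
    df.loc[retained.index, "weight"] = w
    df["relative_likelihood"] = 0.0
    df.loc[retained.index, "relative_likelihood"] = rel
    candidates = retained[np.isclose(retained["AIC"], retained["AIC"].min())]
    best = int(min(candidates.index))  # fewest parameters wins ties (sorted ids)
    return ModelComparison(table=df, best_model=best, excluded=excluded)


def compare_structures(fits: dict[str, FitResult]) -> ModelComparison:
    """Rank same-model fits under alternative taxon-structure labelings.

    All fits share the data and the model (hence the parameter count), so the
    AIC ranking is the logL ranking; weights are reported over all labelings.
    Raises if the fits do not come from the same alignment.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits.values()}
    if len(hashes) != 1:
        raise ValueError("structure fits come from different datasets")
    model_ids = {f.model_id for f in fits.values()}
    if len(model_ids) != 1:
        raise ValueError("structure fits use different models")
    names = list(fits)
    k = count_free_parameters(next(iter(model_ids)))
    aics = [aic(fits[n].log_likelihood, k) for n in names]
    w = aic_weights(aics)
    df = pd.DataFrame({
        "structure": names,
        "logL": [fits[n].log_likelihood for n in names],
        "AIC": aics,
        "deltaAIC": np.asarray(aics) - min(aics),
        "weight": w,
    }).set_index("structure").sort_values("AIC")
    return ModelComparison(table=df, best_model=str(df.index[0]))


def aggregate_best_models(comparisons: dict[str, ModelComparison]) -> pd.DataFrame:
    """Best-model counts across orthogroups (the per-gene tally)."""
    counts: dict[int, int] = {m: 0 for m in (1, 2, 3, 4)}
    for comp in comparisons.values():
        counts[int(comp.best_model)] = counts.get(int(comp.best_model), 0) + 1
    return pd.DataFrame({"model": list(counts), "n_best": list(counts.values())
                         }).set_index("model")


def parameter_distribution(fits_by_group: dict[str, FitResult],
                           parameter: str = "p2a") -> pd.Series:
    """Across-orthogroup distribution of one mixture quantity.

    ``parameter`` may be ``p0``, ``p1``, ``p2a``, ``p2b``, ``omega0`` or
    ``omega2``.
    """
    vals = {}
    for gid, fit in fits_by_group.items():
        if parameter in ("omega0", "omega2"):
            v = getattr(fit.spec, parameter)
        else:
            label = parameter[1:]
            mix = fit.mixture
            if label not in mix.labels:
                continue
            v = float(mix.proportions[mix.labels.index(label)])
        if v is not None:
            vals[gid] = float(v)
    return pd.Series(vals, name=parameter)
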