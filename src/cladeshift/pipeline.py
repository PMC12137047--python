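"""Orchestration of the three analysis tracks with file-based inputs/outputs.

Tracks: (1) fit the four codon models to one concatenated alignment and
produce an AIC comparison table; (2) fit per-orthogroup across a directory of
filtered orthogroups and aggregate best-model counts and parameter
distributions; (3) fit the chosen branch-site model under every alternative
taxon-structure labeling and rank the structures.  Each run writes a manifest
(config hash, seed, version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon import CodonAlignment
from .compare import (
    ModelComparison,
    aggregate_best_models,
    compare_structures,
    parameter_distribution,
    select_best,
)
from .filtering import FilterReport, Orthogroup, filter_batch
from .models import MODEL_NAMES, FitResult, fit_all_models, fit_model
from .trees import (
    BranchLabeling,
    PhyloTree,
    UnitPartition,
    enumerate_structure_hypotheses,
    label_branches,
)

logger = logging.getLogger("cladeshift")


@dataclass
class RunConfig:
    """Validated inputs and options for a pipeline run."""

    alignment: str | None = None
    tree: str | None = None
    partition: str | None = None
    orthogroup_dir: str | None = None
    outdir: str = "cladeshift_out"
    scheme: str = "F3X4"
    models: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    structure_model: int = 3
    n_starts: int = 3
    seed: int = 0
    reoptimize_nuisance: bool = False
    uninformative_tol: float = 1e-3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self, need: tuple[str, ...]) -> None:
        for key in need:
            value = getattr(self, key)
            if value is None:
                raise ValueError(f"config field {key!r} is required for this run")
            if key in ("alignment", "tree", "partition", "orthogroup_dir") \
                    and not Path(value).exists():
                raise FileNotFoundError(f"{key} path does not exist: {value}")

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, extra: dict | None = None):
    manifest = {"config": asdict(config), "config_hash": config.content_hash(),
                "version": __version__, **(extra or {})}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")


def comparison_table(fits: dict[int, FitResult],
                     comparison: ModelComparison) -> pd.DataFrame:
    """Per-model report with the comparison's standard columns."""
    rows = []
    for mid in sorted(fits):
        f = fits[mid]
        mix = {f"p{lb}": p for lb, p, _, _ in f.mixture.as_rows()}
        rows.append({
            "model": mid, "type": MODEL_NAMES[mid],
            "p0": mix.get("p0"), "p1": mix.get("p1"),
            "p2a": mix.get("p2a"), "p2b": mix.get("p2b"),
            "w0": f.spec.omega0, "w1": 1.0, "w2": f.spec.omega2,
            "logL": f.log_likelihood,
            "AIC": float(comparison.table.loc[mid, "AIC"]),
            "AICw": float(comparison.table.loc[mid, "weight"]),
            "excluded": bool(comparison.table.loc[mid, "excluded"]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Track 1: concatenated alignment
# ---------------------------------------------------------------------------

def run_concatenated(config: RunConfig) -> tuple[dict[int, FitResult], ModelComparison]:
    config.validate(("alignment", "tree", "partition"))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = CodonAlignment.from_fasta(config.alignment)
    tree = PhyloTree.from_file(config.tree)
    partition = UnitPartition.from_tsv(config.partition)
    labeling = label_branches(tree, partition)
    fits = fit_all_models(aln, tree, labeling, scheme=config.scheme,
                          model_ids=tuple(config.models),
                          n_starts=config.n_starts, seed=config.seed,
                          reoptimize_nuisance=config.reoptimize_nuisance)
    comparison = select_best(fits, tol=config.uninformative_tol)
    table = comparison_table(fits, comparison)
    table.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False,
                 float_format="%.6g")
    results = {str(m): f.summary() for m, f in fits.items()}
    (outdir / "fits.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float) + "\n")
    _write_manifest(outdir, config, {"track": "concatenated",
                                     "best_model": int(comparison.best_model)})
    return fits, comparison


# ---------------------------------------------------------------------------
# Track 2: per-orthogroup fits
# ---------------------------------------------------------------------------

def load_orthogroup(prefix: Path) -> Orthogroup:
    """Load {prefix}.fasta / {prefix}.nwk / {prefix}.tsv (seq, species, unit)."""
    aln = CodonAlignment.from_fasta(f"{prefix}.fasta")
    tree = PhyloTree.from_file(f"{prefix}.nwk")
    labels = pd.read_csv(f"{prefix}.tsv", sep="\t", header=None,
                         names=["seq", "species", "unit"], dtype=str)
    return Orthogroup(prefix.name, aln, tree,
                      dict(zip(labels["seq"], labels["species"])),
                      dict(zip(labels["seq"], labels["unit"])))


def save_orthogroup(og: Orthogroup, prefix: Path) -> None:
    og.alignment.to_fasta(f"{prefix}.fasta")
    Path(f"{prefix}.nwk").write_text(og.tree.to_newick() + "\n")
    pd.DataFrame(
        [(n, og.species[n], og.units[n]) for n in og.alignment.names]
    ).to_csv(f"{prefix}.tsv", sep="\t", header=False, index=False)


def load_orthogroup_dir(directory) -> list[Orthogroup]:
    directory = Path(directory)
    prefixes = sorted(p.with_suffix("") for p in directory.glob("*.fasta"))
    if not prefixes:
        raise ValueError(f"no orthogroup FASTA files in {directory}")
    return [load_orthogroup(p) for p in prefixes]


def fit_orthogroup(og: Orthogroup, *, scheme: str = "F3X4",
                   model_ids: tuple[int, ...] = (1, 2, 3, 4),
                   n_starts: int = 3, seed: int = 0,
                   tol: float = 1e-3) -> tuple[dict[int, FitResult], ModelComparison]:
    partition = UnitPartition(og.units)
    labeling = label_branches(og.tree, partition)
    try:
        fits = fit_all_models(og.alignment, og.tree, labeling, scheme=scheme,
                              model_ids=model_ids, n_starts=n_starts, seed=seed)
    except RuntimeError:
        logger.warning("retrying orthogroup %s with fresh starts", og.id)
        fits = fit_all_models(og.alignment, og.tree, labeling, scheme=scheme,
                              model_ids=model_ids, n_starts=n_starts,
                              seed=seed + 104729)
    return fits, select_best(fits, tol=tol)


def run_per_orthogroup(config: RunConfig,
                       model_ids: tuple[int, ...] = (1, 2, 3, 4)) -> pd.DataFrame:
    config.validate(("orthogroup_dir",))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = load_orthogroup_dir(config.orthogroup_dir)
    rows = []
    comparisons: dict[str, ModelComparison] = {}
    best_fits: dict[str, FitResult] = {}
    for i, og in enumerate(sorted(groups, key=lambda g: g.id)):
        try:
            fits, comp = fit_orthogroup(
                og, scheme=config.scheme, model_ids=model_ids,
                n_starts=config.n_starts,
                seed=config.seed + _stable_offset(og.id),
                tol=config.uninformative_tol)
        except Exception as exc:
            logger.error("orthogroup %s failed: %s", og.id, exc)
            rows.append({"orthogroup": og.id, "status": "failed",
                         "error": str(exc)})
            continue
        comparisons[og.id] = comp
        best = int(comp.best_model)
        best_fits[og.id] = fits[best]
        f = fits[best]
        mix = {f"p{lb}": p for lb, p, _, _ in f.mixture.as_rows()}
        rows.append({"orthogroup": og.id, "status": "ok", "best_model": best,
                     "AICw": comp.weight(best), **mix,
                     "w0": f.spec.omega0, "w2": f.spec.omega2,
                     "logL": f.log_likelihood})
        logger.info("orthogroup %s: best model %d (%d/%d)", og.id, best,
                    i + 1, len(groups))
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "per_orthogroup.tsv", sep="\t", index=False,
                 float_format="%.6g")
    counts = aggregate_best_models(comparisons)
    counts.to_csv(outdir / "best_model_counts.tsv", sep="\t")
    dist = pd.DataFrame({
        par: parameter_distribution(best_fits, par).describe()
        for par in ("p0", "p2a", "omega0")
    })
    dist.to_csv(outdir / "parameter_distributions.tsv", sep="\t",
                float_format="%.6g")
    _write_manifest(outdir, config, {"track": "per_orthogroup",
                                     "n_orthogroups": len(groups)})
    return table


def _stable_offset(name: str) -> int:
    return int(hashlib.sha256(name.encode()).hexdigest()[:6], 16)


# ---------------------------------------------------------------------------
# Track 3: taxon-structure comparison
# ---------------------------------------------------------------------------

def run_structures(config: RunConfig) -> pd.DataFrame:
    """Fit the chosen branch-site model under the base labeling and all
    lump/split alternatives; rank by AIC and report family-combined weights."""
    config.validate(("alignment", "tree", "partition"))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = CodonAlignment.from_fasta(config.alignment)
    tree = PhyloTree.from_file(config.tree)
    base = UnitPartition.from_tsv(config.partition)
    hypotheses = enumerate_structure_hypotheses(tree, base)
    # shared nuisance: kappa and branch scale from a model-1 fit (labeling-free)
    m1 = fit_model(aln, tree, BranchLabeling.all_background(tree), 1,
                   scheme=config.scheme, n_starts=config.n_starts,
                   seed=config.seed)
    scaled = tree.with_lengths(tree.lengths * m1.branch_scale)
    fits: dict[str, FitResult] = {}
    for hyp in hypotheses:
        lab = BranchLabeling(scaled, hyp.labeling.foreground)
        fits[hyp.name] = fit_model(
            aln, scaled, lab, config.structure_model, scheme=config.scheme,
            kappa=m1.kappa, optimize_scale=False, n_starts=config.n_starts,
            seed=config.seed + _stable_offset(hyp.name))
    comp = compare_structures(fits)
    table = comp.to_frame().reset_index()
    kind_of = {h.name: h.kind for h in hypotheses}
    table["family"] = table["structure"].map(kind_of)
    family_weights = table.groupby("family")["weight"].sum().rename("combined_weight")
    table.to_csv(outdir / "structure_comparison.tsv", sep="\t", index=False,
                 float_format="%.6g")
    family_weights.to_csv(outdir / "structure_family_weights.tsv", sep="\t")
    _write_manifest(outdir, config, {"track": "structures",
                                     "best_structure": str(comp.best_model)})
    return table


# ---------------------------------------------------------------------------
# Filtering track
# ---------------------------------------------------------------------------

def run_filter(config: RunConfig, required_units: list[str] | None = None
               ) -> tuple[list[Orthogroup], FilterReport]:
    config.validate(("orthogroup_dir",))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = load_orthogroup_dir(config.orthogroup_dir)
    if required_units is None:
        required_units = sorted({u for og in groups for u in og.units.values()})
    kept, report = filter_batch(groups, required_units, seed=config.seed)
    for og in kept:
        save_orthogroup(og, outdir / og.id)
    df = report.to_frame()
    df.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    (outdir / "filter_report.json").write_text(
        json.dumps({"records": report.records, "thresholds": report.thresholds},
                   indent=2, default=str) + "\n")
    _write_manifest(outdir, config, {"track": "filter", "n_in": len(groups),
                                     "n_out": len(kept)})
    return kept, report
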