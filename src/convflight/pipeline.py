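"""End-to-end orchestration: simulate/load -> scan -> confirm -> energy model.

A single :class:`PipelineConfig` (constructible from YAML) drives every
stage; one global seed fans out to per-stage seeds by fixed offsets so that
re-running an identical config byte-reproduces all outputs.  Each stage
writes its table under the configured output directory and the run ends
with a JSON manifest recording parameters, seeds and per-stage counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral_codons import reconstruct_codon
from .alphabets import DNA
from .convergence import confirm_candidates, results_to_frame
from .core_io import (
    LabeledAlignment,
    Phylogeny,
    SpeciesGroupTable,
    read_alignment,
    read_labels,
    read_tree,
    write_alignment,
    write_tree,
)
from .energy import KineticParams, sweep
from .models import SubstitutionModel, hky85, jc69, jtt
from .simulate import (
    PlantedSite,
    SimulationConfig,
    simulate_alignment,
)
from .site_scan import candidates_to_frame, scan_alignment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "synthetic_study", "model_by_name"]

# Fixed per-stage seed offsets (reproducibility with stage independence).
_SEED_OFFSETS = {"simulate": 0, "scan": 101, "nulltest": 211, "ancestral": 307, "energy": 401}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def model_by_name(
    name: str, gamma_shape: float | None = None, n_categories: int = 1
) -> SubstitutionModel:
    name = name.lower()
    if name == "jc69":
        return jc69(gamma_shape, n_categories)
    if name == "hky85":
        return hky85(2.0, None, gamma_shape, n_categories)
    if name == "jtt":
        return jtt(None, gamma_shape, n_categories)
    raise ValueError(f"unknown model {name!r} (choose jc69, hky85 or jtt)")


# ---------------------------------------------------------------------- #
# Synthetic study bundles


def synthetic_study(
    n_species: int = 48,
    n_foreground: int = 8,
    n_genes: int = 20,
    n_sites: int = 300,
    n_planted_genes: int = 1,
    planted_sites_per_gene: int = 1,
    seed: int = 0,
    model: SubstitutionModel | None = None,
    mean_branch_length: float = 0.05,
    missing_fraction: float = 0.0,
) -> dict:
    """Generate a labelled study bundle with planted convergence.

    The default shape mirrors the discovery design: 48 species of which 8
    are flight-degenerate, with the foreground species scattered across the
    tree (flight degeneration arose many times independently, so the
    foreground must not form clades: clustered foreground species would
    share states by descent and mimic convergence).  Planted genes carry
    ``planted_sites_per_gene`` sites at which all foreground species share a
    derived state.  Returns a dict with keys ``labels``, ``tree``,
    ``alignments`` (gene -> LabeledAlignment) and ``truth``
    (gene -> TruthTable).
    """
    from .simulate import random_phylogeny

    if not 0 < n_foreground < n_species:
        raise ValueError("need 0 < n_foreground < n_species")
    if model is None:
        model = hky85(2.0, np.array([0.3, 0.2, 0.2, 0.3]), gamma_shape=0.5, n_categories=4)

    rng = np.random.default_rng(seed)
    placeholders = [f"tmp{i:03d}" for i in range(n_species)]
    tree = random_phylogeny(placeholders, seed=seed + 1,
                            mean_branch_length=mean_branch_length)
    # Scatter the foreground: leaves adjacent in the postorder leaf sequence
    # are phylogenetically close, so spreading the flight-degenerate labels
    # evenly along that sequence keeps them on independent lineages.
    leaves = list(tree.tree.leaf_node_iter())
    fg_positions = {round(i * n_species / n_foreground) for i in range(n_foreground)}
    fg, bg = [], []
    for pos, leaf in enumerate(leaves):
        if pos in fg_positions:
            name = f"deg{len(fg) + 1:02d}"
            fg.append(name)
        else:
            name = f"fly{len(bg) + 1:02d}"
            bg.append(name)
        leaf.taxon.label = name
    labels = SpeciesGroupTable(
        {**{s: "flight_degenerate" for s in fg}, **{s: "flying" for s in bg}}
    )

    alignments: dict[str, LabeledAlignment] = {}
    truths: dict[str, object] = {}
    planted_genes = {f"gene{g:03d}" for g in range(1, n_planted_genes + 1)}
    for g in range(1, n_genes + 1):
        gene = f"gene{g:03d}"
        planted: list[PlantedSite] = []
        if gene in planted_genes:
            sites = rng.choice(n_sites, size=planted_sites_per_gene, replace=False) + 1
            for s in sites:
                state = model.alphabet.states[int(rng.integers(model.n_states))]
                planted.append(PlantedSite(int(s), state, frozenset(fg)))
        cfg = SimulationConfig(
            tree=tree,
            model=model,
            labels=labels,
            n_sites=n_sites,
            planted_sites=planted,
            seed=int(seed * 1009 + g) % (2**31),
            missing_fraction=missing_fraction,
            gene_id=gene,
        )
        aln, truth = simulate_alignment(cfg)
        alignments[gene] = aln
        truths[gene] = truth
    return {"labels": labels, "tree": tree, "alignments": alignments, "truth": truths}


# ---------------------------------------------------------------------- #
# Configuration


@dataclass
class PipelineConfig:
    output_dir: str = "convflight_out"
    seed: int = 0
    # either synthetic simulation ...
    simulate: dict | None = None  # kwargs for synthetic_study
    # ... or paths to real inputs
    alignment_dir: str | None = None
    tree_path: str | None = None
    labels_path: str | None = None
    # stage settings
    min_shared: int = 7
    alpha_fisher: float = 1e-3
    alpha_poisson: float = 0.01
    model: str = "hky85"
    gamma_shape: float | None = 0.5
    n_categories: int = 4
    plus_f: bool = True
    energy: dict = field(default_factory=dict)  # KineticParams overrides
    alpha1_sweep: tuple[float, float, int] = (25.0, 10.0, 31)
    alpha3_sweep: tuple[float, float, int] = (1.0, 10.0, 31)
    dominance_criterion: str = "energy"

    def __post_init__(self) -> None:
        for name in ("alpha_fisher", "alpha_poisson"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("alpha1_sweep", "alpha3_sweep"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_inputs(config: PipelineConfig) -> dict:
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed + _SEED_OFFSETS["simulate"])
        return synthetic_study(**sim_kwargs)
    if not (config.alignment_dir and config.tree_path and config.labels_path):
        raise StageError("load", "config must give either 'simulate' or all three input paths")
    labels = read_labels(config.labels_path)
    tree = read_tree(config.tree_path, default_branch_length=0.1)
    alignments = {}
    for path in sorted(Path(config.alignment_dir).glob("*.fa*")):
        aln = read_alignment(path, labels, DNA)
        alignments[aln.gene_id] = aln
    return {"labels": labels, "tree": tree, "alignments": alignments, "truth": {}}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/load -> scan -> confirm -> energy; write tables + manifest.

    Returns the manifest dict.  Any stage failure raises :class:`StageError`
    naming the stage; tables written before the failure are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "convflight",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("output_dir",)
        },
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    bundle = _load_inputs(config)
    alignments: dict[str, LabeledAlignment] = bundle["alignments"]
    tree: Phylogeny = bundle["tree"]
    labels: SpeciesGroupTable = bundle["labels"]
    if config.simulate is not None:
        write_tree(tree, out / "tree.nwk")
        labels.to_tsv(out / "labels.tsv")
        gene_dir = out / "genes"
        gene_dir.mkdir(exist_ok=True)
        for gene, aln in alignments.items():
            write_alignment(aln, gene_dir / f"{gene}.fasta")
        manifest["stages"]["simulate"] = {
            "n_genes": len(alignments),
            "n_planted_genes": sum(1 for t in bundle["truth"].values() if len(t.frame)),
        }

    # --- scan -----------------------------------------------------------
    if not alignments:
        raise StageError("scan", "no alignments to scan")
    candidates = []
    try:
        for gene in sorted(alignments):
            candidates.extend(
                scan_alignment(alignments[gene], config.min_shared, config.alpha_fisher)
            )
    except Exception as exc:
        raise StageError("scan", str(exc)) from exc
    candidates_to_frame(candidates).to_csv(out / "candidates.tsv", sep="\t", index=False)
    manifest["stages"]["scan"] = {
        "n_sites_scanned": int(sum(a.n_sites for a in alignments.values())),
        "n_candidates": len(candidates),
        "n_candidate_genes": len({c.gene_id for c in candidates}),
    }

    # --- null test ------------------------------------------------------
    try:
        model = model_by_name(config.model, config.gamma_shape, config.n_categories)
        results = confirm_candidates(
            candidates, alignments, tree, model,
            alpha=config.alpha_poisson, plus_f=config.plus_f,
        )
    except Exception as exc:
        raise StageError("nulltest", str(exc)) from exc
    results_to_frame(results).to_csv(out / "confirmed.tsv", sep="\t", index=False)
    manifest["stages"]["nulltest"] = {
        "n_tested_genes": len(results),
        "n_retained_genes": sum(r.retained for r in results),
    }

    # --- ancestral calls at retained candidate sites --------------------
    try:
        call_rows = []
        retained_genes = {r.gene_id for r in results if r.retained}
        nt_model = (
            model if model.alphabet.name == "dna"
            else model_by_name("hky85", config.gamma_shape, config.n_categories)
        )
        for cand in candidates:
            if cand.gene_id not in retained_genes:
                continue
            aln = alignments[cand.gene_id]
            if aln.alphabet.name != "dna":
                continue
            start = min(cand.site, max(aln.n_sites - 2, 1))
            rec = reconstruct_codon(aln, start, tree, nt_model)
            codon, pp = rec.root_call()
            from Bio.Seq import Seq

            call_rows.append(
                {
                    "gene_id": cand.gene_id,
                    "site": cand.site,
                    "codon_start": start,
                    "root_codon": codon,
                    "root_pp": pp,
                    "root_aa": str(Seq(codon).translate()),
                }
            )
    except Exception as exc:
        raise StageError("ancestral", str(exc)) from exc
    pd.DataFrame(
        call_rows,
        columns=["gene_id", "site", "codon_start", "root_codon", "root_pp", "root_aa"],
    ).to_csv(out / "calls.tsv", sep="\t", index=False)
    manifest["stages"]["ancestral"] = {"n_calls": len(call_rows)}

    # --- energy model ---------------------------------------------------
    try:
        params = KineticParams(**config.energy) if config.energy else KineticParams()
        a1_lo_hi = config.alpha1_sweep
        grid1 = np.linspace(a1_lo_hi[0], a1_lo_hi[1], int(a1_lo_hi[2]))
        s1 = sweep(params, "alpha1", grid1, criterion=config.dominance_criterion)
        a3 = config.alpha3_sweep
        grid3 = np.linspace(a3[0], a3[1], int(a3[2]))
        params3 = KineticParams(**{**dict(alpha1=10.0), **config.energy})
        s3 = sweep(params3, "alpha3", grid3, criterion=config.dominance_criterion)
    except Exception as exc:
        raise StageError("energy", str(exc)) from exc
    pd.concat([s1.to_frame(), s3.to_frame()], ignore_index=True).to_csv(
        out / "sweep.tsv", sep="\t", index=False
    )
    manifest["stages"]["energy"] = {
        "alpha1_switch": s1.threshold,
        "alpha3_switch": s3.threshold,
    }

    # consistency: confirmed genes are a subset of candidate genes
    assert {r.gene_id for r in results} <= {c.gene_id for c in candidates}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
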