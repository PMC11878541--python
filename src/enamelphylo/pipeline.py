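"""End-to-end synthetic experiments: fragmentation sweeps, case studies,
conservation partitions.

Each experiment simulates a known species tree and protein supermatrix,
derives fragmentation masks from simulated dated peptide sets, infers
trees from the (possibly reduced) data with corrected distances +
neighbor joining, and scores them against the generating tree with
Robinson–Foulds distance and rank monophyly. Every run emits a manifest
(config, seeds, parameter hash) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import conservation as cons
from . import fragmentation as frag
from .models import GammaRateModel
from .msa import ConcatenatedMSA
from .phylo import MissingDistanceError, distance_matrix, neighbor_joining
from .simulate import (
    CORE5,
    DEFAULT_PROTEIN_SITES,
    SimulatedDataset,
    SimulationConfig,
    SurvivalParams,
    simulate_ancient_peptides,
    simulate_dataset,
)
from .treecmp import bipartitions, rf_distance
from .trees import derooted, leaves_below

PROTEIN_SETS: dict[str, tuple[str, ...]] = {
    "5": CORE5,
    "10": CORE5 + ("AHSG", "ALB", "ODAM", "SERPINC1", "TUFT1"),
    "14": tuple(sorted(DEFAULT_PROTEIN_SITES)),
}


@dataclass
class ExperimentConfig:
    """Declarative description of one synthetic experiment."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    protein_set: str | Sequence[str] = "14"
    stage_fractions: dict[str, float] = field(
        default_factory=lambda: {"full": 1.0, **frag.DEFAULT_STAGE_FRACTIONS}
    )
    seeds: Sequence[int] = (0,)
    correction: str = "poisson"
    correction_alpha: float | None = None
    target_taxa: Sequence[str] | None = None
    case_stage: str = "5 Ma"
    window: int = 20
    peptide_ages: Sequence[float] = (0.1, 1.5, 10.0)
    samples_per_age: int = 3
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    force_empty_proteins: Sequence[str] = ("TUFT1",)
    rate_alpha: float | str = "generating"  # or "fit", or a number

    def proteins(self) -> tuple[str, ...]:
        if isinstance(self.protein_set, str):
            return PROTEIN_SETS[self.protein_set]
        return tuple(self.protein_set)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        survival = SurvivalParams(**raw.pop("survival", {}))
        return cls(sim=sim, survival=survival, **raw)


@dataclass
class Manifest:
    config: dict
    seeds: list[int]
    param_hash: str

    @classmethod
    def build(cls, config: ExperimentConfig) -> "Manifest":
        as_dict = json.loads(json.dumps(dataclasses.asdict(config), default=str))
        digest = hashlib.sha256(
            json.dumps(as_dict, sort_keys=True).encode()
        ).hexdigest()[:16]
        return cls(as_dict, list(config.seeds), digest)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sub_seed(seed: int, *salt: int) -> int:
    return int(np.random.SeedSequence([seed, *salt]).generate_state(1)[0] % (2**31))


@dataclass
class Scenario:
    dataset: SimulatedDataset
    profile: frag.CoverageProfile
    masks: dict[str, frag.StageMask]


def build_scenario(config: ExperimentConfig, seed: int) -> Scenario:
    """Simulate alignment + dated peptides and derive the stage masks."""
    proteins = config.proteins()
    sim = dataclasses.replace(
        config.sim,
        seed=seed,
        n_sites_per_protein={
            p: config.sim.n_sites_per_protein[p] for p in proteins
        },
    )
    dataset = simulate_dataset(sim)
    anchor = dataset.msa.taxa[0]
    mapped = []
    skip = set(config.force_empty_proteins)
    for ai, age in enumerate(config.peptide_ages):
        for s in range(config.samples_per_age):
            peptides = []
            for pi, protein in enumerate(proteins):
                if protein in skip:
                    continue
                start, end = dataset.msa.partitions[protein]
                row = dataset.msa.row(anchor)[start:end]
                ps = simulate_ancient_peptides(
                    row, protein, age, config.survival,
                    seed=_sub_seed(seed, 1, ai, s, pi),
                    sample_id=f"sample_a{age:g}_{s}",
                )
                peptides.extend(ps.peptides)
            sample = frag.AncientPeptideSet(f"sample_a{age:g}_{s}", age, peptides)
            mapped.append(frag.map_peptides_to_columns(sample, dataset.msa, anchor))
    profile = frag.build_coverage_profile(mapped, dataset.msa)
    defs = [
        frag.StageDefinition(label, target_fraction=fracn)
        for label, fracn in config.stage_fractions.items()
    ]
    masks = frag.build_stage_masks(profile, defs, force_empty=skip)
    return Scenario(dataset, profile, {m.stage: m for m in masks})


def _infer_tree(msa: ConcatenatedMSA, config: ExperimentConfig) -> dendropy.Tree:
    dm = distance_matrix(msa, config.correction, config.correction_alpha)
    return neighbor_joining(dm)


# ---------------------------------------------------------------------------
# fragmentation-stage sweep
# ---------------------------------------------------------------------------

@dataclass
class StageOutcome:
    seed: int
    stage: str
    width: int
    retained_fraction: float
    rf: int | None
    failed: bool = False
    error: str | None = None


@dataclass
class FragmentationReport:
    outcomes: list[StageOutcome]
    manifest: Manifest

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.outcomes])

    def mean_rf_by_stage(self) -> dict[str, float]:
        df = self.to_frame()
        ok = df[~df["failed"]]
        return ok.groupby("stage", sort=False)["rf"].mean().to_dict()


def run_fragmentation_experiment(config: ExperimentConfig) -> FragmentationReport:
    """Infer one tree per fragmentation stage per seed; score RF to truth.

    Stages producing unbuildable trees (taxon pairs without comparable
    sites, realistic at the oldest stage) are marked failed; the sweep
    continues.
    """
    outcomes = []
    for seed in config.seeds:
        scenario = build_scenario(config, seed)
        msa = scenario.dataset.msa
        for stage, fracn in config.stage_fractions.items():
            mask = scenario.masks[stage]
            reduced = frag.apply_mask_global(msa, mask)
            outcome = StageOutcome(
                seed, stage, reduced.width, reduced.width / msa.width, None
            )
            try:
                tree = _infer_tree(reduced, config)
                outcome.rf = rf_distance(tree, scenario.dataset.tree)
            except (MissingDistanceError, ValueError) as exc:
                outcome.failed = True
                outcome.error = str(exc)
            outcomes.append(outcome)
    return FragmentationReport(outcomes, Manifest.build(config))


# ---------------------------------------------------------------------------
# case studies
# ---------------------------------------------------------------------------

def true_sister_clade(true_tree: dendropy.Tree, target: str) -> frozenset[str]:
    """Leaves of the target's sister clade in the generating tree."""
    t = derooted(true_tree)
    leaf = next(
        lf for lf in t.leaf_node_iter() if lf.taxon.label == target
    )
    parent = leaf.parent_node
    siblings = [c for c in parent.child_nodes() if c is not leaf]
    if parent is t.seed_node and len(siblings) > 1:
        # unrooted trifurcation: take the smaller neighbouring clade
        siblings.sort(key=lambda c: len(leaves_below(c)))
        siblings = siblings[:1]
    out: set[str] = set()
    for s in siblings:
        out |= leaves_below(s)
    return frozenset(out)


@dataclass
class CasePlacement:
    seed: int
    target: str
    placed_with_sister: bool | None  # None = unplaceable
    error: str | None = None


@dataclass
class CaseStudyReport:
    placements: list[CasePlacement]
    manifest: Manifest

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.placements])

    def placement_rate(self) -> float:
        flags = [p.placed_with_sister for p in self.placements if p.placed_with_sister is not None]
        return float(np.mean(flags)) if flags else float("nan")


def run_case_study(config: ExperimentConfig) -> CaseStudyReport:
    """Fragment only the target taxa and test their phylogenetic placement.

    A target is placed correctly when the inferred tree contains the
    split grouping it with its true sister clade from the generating
    tree. Targets whose fragmented rows leave no comparable sites are
    reported unplaceable rather than crashing the run.
    """
    placements = []
    for seed in config.seeds:
        scenario = build_scenario(config, seed)
        msa = scenario.dataset.msa
        targets = list(config.target_taxa) if config.target_taxa else [msa.taxa[-1]]
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate target taxa")
        mask = scenario.masks[config.case_stage]
        mixed = frag.apply_mask_case_study(msa, mask, targets)
        for target in targets:
            sister = true_sister_clade(scenario.dataset.tree, target)
            try:
                tree = _infer_tree(mixed, config)
            except (MissingDistanceError, ValueError) as exc:
                placements.append(CasePlacement(seed, target, None, str(exc)))
                continue
            side = frozenset({target} | sister)
            n = msa.n_taxa
            if len(side) >= n - 1:
                placed = True  # trivial split, nothing to test
            else:
                all_leaves = frozenset(msa.taxa)
                canonical = side if min(all_leaves) not in side else all_leaves - side
                placed = canonical in bipartitions(tree)
            placements.append(CasePlacement(seed, target, placed))
    return CaseStudyReport(placements, Manifest.build(config))


# ---------------------------------------------------------------------------
# conservation partitions
# ---------------------------------------------------------------------------

@dataclass
class PartitionOutcome:
    seed: int
    method: str  # entropy | rate
    subset: str  # variable | conserved | full
    width: int
    rf: int | None
    skipped: bool = False
    error: str | None = None


@dataclass
class PartitionReport:
    outcomes: list[PartitionOutcome]
    manifest: Manifest

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.outcomes])

    def mean_rf(self, method: str, subset: str) -> float:
        vals = [
            o.rf for o in self.outcomes
            if o.method == method and o.subset == subset and not o.skipped
        ]
        return float(np.mean(vals)) if vals else float("nan")


def run_conservation_partition_experiment(config: ExperimentConfig) -> PartitionReport:
    """Split sites into variable/conserved per scoring method; infer both trees.

    Scores are normalized to mean one within each protein, sites with
    score >= 1 are "variable", the rest "conserved"; each subset (plus
    the full alignment) gets a distance + neighbor-joining tree scored
    against the generating tree.
    """
    outcomes = []
    for seed in config.seeds:
        scenario = build_scenario(config, seed)
        msa = scenario.dataset.msa
        guide_tree = _infer_tree(msa, config)

        if config.rate_alpha == "fit":
            gamma = cons.estimate_alpha(msa, guide_tree)
        elif config.rate_alpha == "generating":
            gamma = GammaRateModel(alpha=config.sim.gamma_shape, k=16)
        else:
            gamma = GammaRateModel(alpha=float(config.rate_alpha), k=16)

        tracks = {
            "entropy": cons.entropy_track(msa),
            "rate": cons.site_rates_eb(msa, guide_tree, gamma).raw,
        }
        rf_full = rf_distance(guide_tree, scenario.dataset.tree)
        for method, track in tracks.items():
            outcomes.append(
                PartitionOutcome(seed, method, "full", msa.width, rf_full)
            )
            norm = cons.normalize_mean_one_per_protein(track, msa.partitions)
            variable, conserved = cons.partition_sites(norm)
            for subset, cols in (("variable", variable), ("conserved", conserved)):
                if cols.size == 0:
                    warnings.warn(f"empty {subset} partition for {method}", stacklevel=2)
                    outcomes.append(
                        PartitionOutcome(seed, method, subset, 0, None, skipped=True)
                    )
                    continue
                sub = msa.take_columns(cols)
                outcome = PartitionOutcome(seed, method, subset, sub.width, None)
                try:
                    tree = _infer_tree(sub, config)
                    outcome.rf = rf_distance(tree, scenario.dataset.tree)
                except (MissingDistanceError, ValueError) as exc:
                    outcome.skipped = True
                    outcome.error = str(exc)
                outcomes.append(outcome)
    return PartitionReport(outcomes, Manifest.build(config))
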