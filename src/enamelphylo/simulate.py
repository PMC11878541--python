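"""Synthetic data with the statistical structure the pipeline assumes.

Everything downstream is testable without real data by simulating

* a birth (Yule) species tree with contemporaneous tips,
* protein alignments evolved along it under a reversible amino-acid
  chain with gamma-distributed site rates (the latent truth for rate
  estimation),
* a toy genome, CDS annotation and per-individual variant files whose
  translation reproduces those proteins exactly, and
* dated ancient-peptide sets whose per-site survival decays with sample
  age, emulating post-mortem enamel proteome fragmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
from scipy.special import expit

from .alphabet import AA20, N_STATES
from .fragmentation import AncientPeptideSet, Peptide
from .models import SubstitutionModel
from .msa import ConcatenatedMSA

#: the 14 enamel-associated proteins of the study system, with alignment
#: widths at a 1:7 scale-down of the human protein lengths (relative sizes
#: preserved; desk-scale default)
DEFAULT_PROTEIN_SITES: dict[str, int] = {
    "AHSG": 52, "ALB": 87, "AMBN": 63, "AMELX": 27, "AMTN": 30,
    "COL17A1": 214, "COL1A1": 209, "COL1A2": 195, "COL2A1": 212,
    "ENAM": 163, "MMP20": 69, "ODAM": 40, "SERPINC1": 66, "TUFT1": 55,
}

#: the five-protein core set consistently recovered from fossil enamel
CORE5 = ("AMBN", "AMELX", "AMTN", "ENAM", "MMP20")


@dataclass
class SimulationConfig:
    """Conditions for one synthetic dataset.

    ``tree_height`` is the expected root-to-tip path length in substitutions
    per site; ``gamma_shape`` is the shape of the mean-one gamma site-rate
    distribution (smaller = more rate heterogeneity).
    """

    n_taxa: int = 16
    n_sites_per_protein: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_SITES)
    )
    gamma_shape: float = 0.5
    birth_rate: float = 1.0
    tree_height: float = 0.3
    seed: int = 0
    alphabet: str = AA20

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if any(v <= 0 for v in self.n_sites_per_protein.values()):
            raise ValueError("all per-protein site counts must be positive")
        if len(self.alphabet) != N_STATES:
            raise ValueError("alphabet must have 20 symbols")

    @property
    def total_sites(self) -> int:
        return sum(self.n_sites_per_protein.values())


@dataclass
class TrueHistory:
    """Latent truth of a simulated alignment: tree, site rates, root sequence."""

    tree: dendropy.Tree
    site_rates: np.ndarray
    ancestral_sequence: str

    def __post_init__(self) -> None:
        self.site_rates = np.asarray(self.site_rates, dtype=float)
        if len(self.ancestral_sequence) != self.site_rates.size:
            raise ValueError("site_rates length must equal alignment width")
        if (self.site_rates <= 0).any():
            raise ValueError("site rates must be positive")
        if abs(self.site_rates.mean() - 1.0) > 0.02:
            raise ValueError("site rates must average to 1 (within 2%)")


def simulate_yule_tree(
    n_taxa: int, birth_rate: float, seed: int, height: float | None = None
) -> dendropy.Tree:
    """Pure-birth species tree with ``n_taxa`` contemporaneous tips.

    Lineages split at total rate (number alive) x ``birth_rate``; the
    process stops one exponential waiting time after the last split, so
    the tree is ultrametric. ``height`` optionally rescales branch
    lengths so the root-to-tip depth equals it (substitutions/site).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))

    root = dendropy.Node()
    birth_time = {id(root): 0.0}
    order = {id(root): 0}
    active = [root]
    t = 0.0
    counter = 1
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent_t = birth_time[id(parent)]
        parent.edge.length = None  # set when this node itself was attached
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[id(child)] = t
            order[id(child)] = counter
            counter += 1
            active.append(child)
        # edge length of parent = t - its own birth time
        if parent is not root:
            parent.edge.length = t - parent_t
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    names = {}
    for leaf in sorted(active, key=lambda nd: order[id(nd)]):
        leaf.edge.length = t_end - birth_time[id(leaf)]
        names[id(leaf)] = f"T{len(names) + 1:0{width}d}"

    tns = dendropy.TaxonNamespace(sorted(names.values()))
    for leaf in active:
        leaf.taxon = tns.get_taxon(names[id(leaf)])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    if height is not None:
        # ultrametric: every tip sits at the same depth below the root split
        leaf = active[0]
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length
            node = node.parent_node
        scale = height / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def balanced_tree(n_taxa: int, branch_length: float = 0.05) -> dendropy.Tree:
    """Fully balanced binary tree with uniform branch lengths.

    Useful for identifiability-controlled experiments: unlike a random
    birth tree, no internal branch is vanishingly short, so every split
    is resolvable from a long enough alignment. ``n_taxa`` must be a
    power of two.
    """
    if n_taxa < 4 or n_taxa & (n_taxa - 1):
        raise ValueError("n_taxa must be a power of two >= 4")
    names = [f"T{i + 1:0{len(str(n_taxa))}d}" for i in range(n_taxa)]

    def clade(sub: list[str]) -> str:
        if len(sub) == 1:
            return f"{sub[0]}:{branch_length}"
        h = len(sub) // 2
        return f"({clade(sub[:h])},{clade(sub[h:])}):{branch_length}"

    h = n_taxa // 2
    newick = f"({clade(names[:h])},{clade(names[h:])});"
    from .trees import tree_from_newick

    return tree_from_newick(newick, rooted=True)


def evolve_alignment(
    tree: dendropy.Tree,
    n_sites: int | Mapping[str, int],
    gamma_shape: float | None,
    model: SubstitutionModel | None = None,
    seed: int = 0,
) -> tuple[ConcatenatedMSA, TrueHistory]:
    """Evolve a gap-free protein alignment along a tree.

    Site rates are i.i.d. Gamma(shape, mean 1) draws rescaled to unit
    empirical mean (``gamma_shape=None`` means homogeneous rates); each
    branch applies a reversible substitution chain for branch length x
    site rate expected substitutions. ``n_sites`` may be a per-protein
    mapping, in which case the partition map is populated accordingly.
    """
    if model is None:
        model = SubstitutionModel()
    if isinstance(n_sites, Mapping):
        partitions = {}
        pos = 0
        for name, w in n_sites.items():
            partitions[name] = (pos, pos + int(w))
            pos += int(w)
        total = pos
    else:
        total = int(n_sites)
        partitions = {"all": (0, total)}
    if total <= 0:
        raise ValueError("alignment must have at least one site")

    rng = np.random.default_rng(seed)
    if gamma_shape is None or math.isinf(gamma_shape):
        rates = np.ones(total)
    else:
        if gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        rates = rng.gamma(shape=gamma_shape, scale=1.0 / gamma_shape, size=total)
        rates = np.maximum(rates, 1e-12)
        rates /= rates.mean()

    def sample_rows(prob_rows: np.ndarray) -> np.ndarray:
        cum = prob_rows.cumsum(axis=1)
        cum /= cum[:, -1:]
        u = rng.random((prob_rows.shape[0], 1))
        return (cum < u).sum(axis=1).clip(max=N_STATES - 1)

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(N_STATES, size=total, p=model.freqs)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        b = node.edge.length
        if b is None or b < 0:
            raise ValueError("every non-root branch needs a non-negative length")
        parent_states = states[id(node.parent_node)]
        if b == 0:
            states[id(node)] = parent_states.copy()
            continue
        p_mats = model.transition_matrices(b * rates)  # (total, 20, 20)
        probs = p_mats[np.arange(total), parent_states]
        states[id(node)] = sample_rows(probs)

    symbols = np.array(list(AA20))
    rows = {
        lf.taxon.label: "".join(symbols[states[id(lf)]])
        for lf in tree.leaf_node_iter()
    }
    rows = {name: rows[name] for name in sorted(rows)}
    msa = ConcatenatedMSA.from_rows(rows, partitions=partitions)
    history = TrueHistory(tree, rates, "".join(symbols[states[id(root)]]))
    return msa, history


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    msa: ConcatenatedMSA
    history: TrueHistory


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Tree + alignment + latent truth from one :class:`SimulationConfig`."""
    tree = simulate_yule_tree(
        config.n_taxa, config.birth_rate, config.seed, height=config.tree_height
    )
    msa, history = evolve_alignment(
        tree, config.n_sites_per_protein, config.gamma_shape, seed=config.seed + 1
    )
    return SimulatedDataset(config, tree, msa, history)


# ---------------------------------------------------------------------------
# back-translation to genome / annotation / variants
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _codon_map() -> dict[str, list[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


@dataclass
class EmittedGenome:
    """Paths and layout of a back-translated toy genome."""

    reference_fasta: Path
    gff: Path
    vcfs: dict[str, Path]  # individual -> VCF path (reference individual absent)
    reference_individual: str
    contig: str
    genes: list[str]


def backtranslate_and_emit(
    msa: ConcatenatedMSA,
    outdir,
    codon_table: Mapping[str, list[str]] | None = None,
    seed: int = 0,
) -> EmittedGenome:
    """Turn a gap-free protein MSA into reference FASTA + GFF3 + VCFs.

    The first taxon's codons become the reference genome (one contig,
    genes laid out with short spacers, alternating strands); every other
    taxon's codon differences are emitted as haploid homozygous SNVs in a
    per-individual VCF. Codons are assigned per (column, residue), so
    identical residues never generate variants and a full round trip
    through proteome prediction reproduces the input alignment.
    """
    from .alphabet import ABSENT

    if any(c in ABSENT for row in msa.seqs for c in row):
        raise ValueError("back-translation requires a gap-free alignment")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if codon_table is None:
        codon_table = _codon_map()
    rng = np.random.default_rng(seed)
    contig = "chr1"
    ref_taxon = msa.taxa[0]
    spacer_len = 20

    # one codon choice per (column, residue)
    col_codons: list[dict[str, str]] = []
    for j in range(msa.width):
        residues = sorted(set(msa.seqs[:, j]))
        chosen = {}
        for aa in residues:
            options = codon_table.get(aa)
            if not options:
                raise RuntimeError(f"no codon available for residue {aa!r}")
            chosen[aa] = options[int(rng.integers(len(options)))]
        col_codons.append(chosen)

    def cds_of(taxon: str, protein: str) -> str:
        start, end = msa.partitions[protein]
        i = msa.taxa.index(taxon)
        codons = [col_codons[j][msa.seqs[i, j]] for j in range(start, end)]
        return "".join(codons) + "TAA"

    # genome layout
    genome_parts: list[str] = []
    gene_coords: dict[str, tuple[int, int, str]] = {}  # 1-based inclusive
    pos = 0
    bases = np.array(list("ACGT"))
    for gi, protein in enumerate(msa.partitions):
        spacer = "".join(bases[rng.integers(4, size=spacer_len)])
        genome_parts.append(spacer)
        pos += spacer_len
        strand = "+" if gi % 2 == 0 else "-"
        cds = cds_of(ref_taxon, protein)
        segment = cds if strand == "+" else _revcomp(cds)
        genome_parts.append(segment)
        gene_coords[protein] = (pos + 1, pos + len(segment), strand)
        pos += len(segment)
    genome_parts.append("".join(bases[rng.integers(4, size=spacer_len)]))
    genome = "".join(genome_parts)

    ref_path = outdir / "reference.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{contig}\n")
        for k in range(0, len(genome), 70):
            fh.write(genome[k : k + 70] + "\n")

    gff_path = outdir / "annotation.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for protein, (start, end, strand) in gene_coords.items():
            attrs_gene = f"ID=gene_{protein};Name={protein}"
            attrs_cds = f"ID=cds_{protein};Parent=gene_{protein};protein={protein}"
            fh.write(
                f"{contig}\tenamelphylo\tgene\t{start}\t{end}\t.\t{strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{contig}\tenamelphylo\tCDS\t{start}\t{end}\t.\t{strand}\t0\t{attrs_cds}\n"
            )

    vcfs: dict[str, Path] = {}
    for taxon in msa.taxa[1:]:
        records: list[tuple[int, str, str]] = []
        for protein, (gstart, gend, strand) in gene_coords.items():
            ref_cds = cds_of(ref_taxon, protein)
            alt_cds = cds_of(taxon, protein)
            for k, (a, b) in enumerate(zip(ref_cds, alt_cds)):
                if a == b:
                    continue
                if strand == "+":
                    gpos = gstart + k
                    ref_base, alt_base = a, b
                else:
                    gpos = gend - k
                    ref_base = a.translate(_COMPLEMENT)
                    alt_base = b.translate(_COMPLEMENT)
                records.append((gpos, ref_base, alt_base))
        records.sort()
        path = outdir / f"{taxon}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig},length={len(genome)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                f"{taxon}\n"
            )
            for gpos, ref_base, alt_base in records:
                fh.write(
                    f"{contig}\t{gpos}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t.\tGT\t1\n"
                )
        vcfs[taxon] = path

    return EmittedGenome(
        ref_path, gff_path, vcfs, ref_taxon, contig, list(msa.partitions)
    )


# ---------------------------------------------------------------------------
# ancient peptide simulation
# ---------------------------------------------------------------------------

@dataclass
class SurvivalParams:
    """Age-dependent per-site peptide survival model.

    Survival probability of site i at sample age a (Ma) is logistic in
    log-age: ``expit(c_i - age_slope * ln(a / age_scale))`` with
    site-specific intercepts ``c_i ~ Normal(intercept_mean,
    intercept_sd)``; age zero survives with probability one. Sites lost
    faster than others emulate the heterogeneous post-mortem survival of
    enamel peptides. ``cleavage_rate`` is the per-boundary probability of
    an in-vivo proteolytic cut that splits surviving runs into shorter
    peptides (the enamel matrix is enzymatically processed in vivo).
    """

    intercept_mean: float = -1.5
    intercept_sd: float = 1.5
    age_slope: float = 1.0
    age_scale: float = 1.0
    cleavage_rate: float = 0.05

    def survival_probabilities(self, n_sites: int, age: float, rng) -> np.ndarray:
        if age < 0:
            raise ValueError("sample age must be non-negative")
        c = rng.normal(self.intercept_mean, self.intercept_sd, size=n_sites)
        if age == 0:
            return np.ones(n_sites)
        return expit(c - self.age_slope * math.log(age / self.age_scale))


def simulate_ancient_peptides(
    protein_row: str,
    protein: str,
    sample_age: float,
    survival_params: SurvivalParams | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> AncientPeptideSet:
    """Simulate the peptides recovered from one protein of a dated sample.

    Each residue survives independently with the age-dependent
    probability of ``survival_params``; peptides are the maximal
    surviving runs, additionally split at in-vivo cleavage points.
    """
    if sample_age < 0:
        raise ValueError("sample age must be non-negative")
    if survival_params is None:
        survival_params = SurvivalParams()
    rng = np.random.default_rng(seed)
    n = len(protein_row)
    p = survival_params.survival_probabilities(n, sample_age, rng)
    surviving = rng.random(n) < p
    cut_after = rng.random(max(n - 1, 0)) < survival_params.cleavage_rate

    peptides: list[Peptide] = []
    start = None
    for i in range(n):
        if not surviving[i]:
            continue
        if start is None:
            start = i
        run_ends = i == n - 1 or not surviving[i + 1] or cut_after[i]
        if run_ends:
            peptides.append(Peptide(protein_row[start : i + 1], protein, start))
            start = None
    if sample_id is None:
        sample_id = f"{protein}_age{sample_age:g}"
    return AncientPeptideSet(sample_id, sample_age, peptides)
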