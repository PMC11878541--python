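"""Per-individual protein prediction from reference + annotation + variants.

The workflow mirrors consensus-based proteome prediction from resequencing
data: splice the annotated CDS out of the reference, substitute each
individual's SNVs, mark unreliable positions as ``N`` at the nucleotide
level, and translate with the standard genetic code, masking every codon
that contains an ``N`` as ``X``. Indels are skipped (with a warning)
rather than applied — frameshift-induced spurious variation is excluded
from this analysis — and variants outside the CDS are ignored.

Internal coordinates are 0-based half-open; GFF and VCF positions are
converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable

from .alphabet import MASK, STOP

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GeneModel:
    """One protein-coding gene: contig, ordered CDS exons, strand, phase."""

    name: str
    contig: str
    exons: list[tuple[int, int]]  # 1-based inclusive, ascending genomic order
    strand: str
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS exons in gene {self.name!r}")
        self.exons = exons
        if (self.cds_length - self.phase) % 3 != 0:
            raise ValueError(
                f"CDS length of {self.name!r} not divisible by 3 after phase"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GenomicAnnotation:
    genes: dict[str, GeneModel]

    @classmethod
    def from_gff(cls, path) -> "GenomicAnnotation":
        """Read CDS features from GFF3, grouped by protein/gene name."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        collected: dict[str, dict] = {}
        for feat in db.features_of_type("CDS"):
            name = None
            for key in ("protein", "gene_name", "Name"):
                if key in feat.attributes:
                    name = feat.attributes[key][0]
                    break
            if name is None and "Parent" in feat.attributes:
                name = feat.attributes["Parent"][0].removeprefix("gene_")
            if name is None:
                name = feat.id
            entry = collected.setdefault(
                name, {"contig": feat.seqid, "strand": feat.strand, "exons": [],
                       "phase": None},
            )
            entry["exons"].append((feat.start, feat.end, feat.frame))
        genes = {}
        for name, entry in collected.items():
            exons = sorted((s, e) for s, e, _ in entry["exons"])
            # phase of the transcript-first exon
            first = exons[-1] if entry["strand"] == "-" else exons[0]
            frame = next(f for s, e, f in entry["exons"] if (s, e) == first)
            phase = int(frame) if frame not in (None, ".", "") else 0
            genes[name] = GeneModel(name, entry["contig"], exons, entry["strand"], phase)
        return cls(genes)


@dataclass
class VariantCall:
    """One VCF record for one individual (SNV or indel)."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    gt: tuple  # allele indices; None for missing
    passed: bool = True

    def resolve_allele(self, het_policy: str = "first") -> str | None:
        """Allele string for this individual; None means mask as 'N'."""
        if not self.passed:
            return None
        called = [a for a in self.gt if a is not None]
        if not called:
            return None
        if len(set(called)) > 1:
            if het_policy == "mask":
                return None
            if het_policy != "first":
                raise ValueError(f"unknown het policy {het_policy!r}")
        idx = called[0]
        return self.ref if idx == 0 else self.alts[idx - 1]


def read_vcf(path, sample: str | None = None) -> list[VariantCall]:
    """Load one individual's calls from a VCF (plain text or bgzipped)."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise ValueError("VCF has multiple samples; name one explicitly")
            sample = samples[0]
        for rec in vf:
            gt = rec.samples[sample].get("GT", (None,))
            if gt is None:
                gt = (None,)
            passed = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
            calls.append(
                VariantCall(
                    rec.contig, rec.pos, rec.ref, tuple(rec.alts or ()), tuple(gt), passed
                )
            )
    return calls


def load_reference(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def apply_variants_to_cds(
    reference: Mapping[str, str],
    gene: GeneModel,
    variants: Iterable[VariantCall],
    het_policy: str = "first",
) -> str:
    """Spliced, strand-oriented CDS with an individual's SNVs applied.

    Missing or non-PASS genotypes become ``N``; indel records inside the
    CDS are skipped with a warning; variants outside the CDS are ignored.
    """
    if gene.contig not in reference:
        raise ValueError(f"contig {gene.contig!r} absent from reference")
    contig_seq = reference[gene.contig]
    pieces = []
    pos_index: dict[int, tuple[int, int]] = {}  # genomic pos -> (piece, offset)
    for k, (s, e) in enumerate(gene.exons):
        if e > len(contig_seq):
            raise ValueError(f"exon {s}-{e} of {gene.name!r} beyond contig end")
        pieces.append(list(contig_seq[s - 1 : e]))
        for off, gpos in enumerate(range(s, e + 1)):
            pos_index[gpos] = (k, off)

    for var in variants:
        if var.contig != gene.contig or var.pos not in pos_index:
            continue
        allele = var.resolve_allele(het_policy)
        if allele is None:
            k, off = pos_index[var.pos]
            pieces[k][off] = "N"
            continue
        if len(var.ref) != 1 or len(allele) != 1:
            warnings.warn(
                f"skipping indel at {var.contig}:{var.pos} in {gene.name!r}",
                stacklevel=2,
            )
            continue
        k, off = pos_index[var.pos]
        pieces[k][off] = allele
    cds = "".join("".join(p) for p in pieces)
    if gene.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds[gene.phase :]


@dataclass
class TranslationFlags:
    internal_stop: bool = False
    length_mismatch: bool = False


def translate_cds(cds: str, flags: TranslationFlags | None = None) -> str:
    """Standard-genetic-code translation with N-codon masking.

    Any codon containing ``N`` becomes ``X``; a trailing stop codon is
    stripped; internal stops translate to ``*`` and set the
    internal-stop flag. The CDS length must be a multiple of 3.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    residues = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            residues.append(MASK)
        elif codon in _STANDARD_TABLE.stop_codons:
            residues.append(STOP)
        else:
            residues.append(_STANDARD_TABLE.forward_table[codon])
    if residues and residues[-1] == STOP:
        residues.pop()
    if flags is not None and STOP in residues:
        flags.internal_stop = True
    return "".join(residues)


@dataclass
class PredictedProtein:
    individual: str
    protein: str
    sequence: str
    flags: TranslationFlags = field(default_factory=TranslationFlags)


@dataclass
class ProteomePrediction:
    proteins: dict[tuple[str, str], PredictedProtein]  # (individual, gene) -> protein
    errors: list[tuple[str, str]]  # (gene, message)

    def rows_for_gene(self, gene: str) -> dict[str, str]:
        return {
            ind: pp.sequence
            for (ind, g), pp in self.proteins.items()
            if g == gene
        }

    def write_fastas(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genes = sorted({g for _, g in self.proteins})
        for gene in genes:
            with open(outdir / f"{gene}.fa", "w") as fh:
                for ind, seq in sorted(self.rows_for_gene(gene).items()):
                    fh.write(f">{ind}\n{seq}\n")


def predict_proteome(
    reference: Mapping[str, str] | str | Path,
    annotation: GenomicAnnotation | str | Path,
    vcfs: Mapping[str, str | Path | None],
    genes: Iterable[str] | None = None,
    het_policy: str = "first",
) -> ProteomePrediction:
    """Predict one protein per (individual, gene).

    ``vcfs`` maps individual id to its VCF path (``None`` = no variants,
    i.e. the reference sequence). A gene absent from the annotation
    produces an error entry; the remaining genes are still predicted.
    """
    if not isinstance(reference, Mapping):
        reference = load_reference(reference)
    if not isinstance(annotation, GenomicAnnotation):
        annotation = GenomicAnnotation.from_gff(annotation)
    gene_list = list(genes) if genes is not None else list(annotation.genes)

    variant_cache: dict[str, list[VariantCall]] = {}
    for ind, path in vcfs.items():
        variant_cache[ind] = read_vcf(path, sample=ind) if path is not None else []

    proteins: dict[tuple[str, str], PredictedProtein] = {}
    errors: list[tuple[str, str]] = []
    for gene in gene_list:
        model = annotation.genes.get(gene)
        if model is None:
            errors.append((gene, "gene absent from annotation"))
            continue
        for ind in vcfs:
            cds = apply_variants_to_cds(
                reference, model, variant_cache[ind], het_policy
            )
            flags = TranslationFlags()
            seq = translate_cds(cds, flags)
            proteins[(ind, gene)] = PredictedProtein(ind, gene, seq, flags)
    return ProteomePrediction(proteins, errors)
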