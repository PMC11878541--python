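"""Concatenated multiple sequence alignments and supermatrix operations.

The central container is :class:`ConcatenatedMSA`: an aligned residue
matrix for named taxa together with a partition map recording which
column interval belongs to which protein, and per-column provenance
(the original column index before any trimming or masking).

Operations cover the supermatrix workflow for enamel-proteome
phylogenetics: picking one representative individual per species,
stripping signal peptides, concatenating per-protein alignments,
gap-fraction trimming, and filling outgroup gaps with the column
consensus so the outgroup can serve as a complete reference row.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import ABSENT, GAP, MASK, MISSING


@dataclass
class ConcatenatedMSA:
    """Aligned residue matrix with a protein partition map.

    Parameters
    ----------
    taxa:
        Unique row labels (species or individual ids).
    seqs:
        Character matrix of shape ``(len(taxa), n_columns)``, dtype ``<U1``,
        over the 20 amino acids plus ``-``, ``X``, ``?``.
    partitions:
        Ordered mapping ``protein name -> (start, end)`` of 0-based
        half-open column intervals; intervals must be disjoint and cover
        every column.
    col_sources:
        Original column index of each current column (provenance through
        trimming/fragmentation). Defaults to ``0..n_columns-1``.
    """

    taxa: list[str]
    seqs: np.ndarray
    partitions: dict[str, tuple[int, int]]
    col_sources: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.seqs = np.asarray(self.seqs, dtype="<U1")
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.taxa):
            raise ValueError("seqs must be a 2D matrix with one row per taxon")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        if self.col_sources is None:
            self.col_sources = np.arange(self.seqs.shape[1])
        self.col_sources = np.asarray(self.col_sources, dtype=np.int64)
        if self.col_sources.shape != (self.seqs.shape[1],):
            raise ValueError("col_sources length must equal column count")
        self._check_partitions()

    def _check_partitions(self) -> None:
        covered = np.zeros(self.width, dtype=bool)
        for name, (start, end) in self.partitions.items():
            if not (0 <= start <= end <= self.width):
                raise ValueError(f"partition {name!r} interval out of bounds")
            if covered[start:end].any():
                raise ValueError(f"partition {name!r} overlaps another partition")
            covered[start:end] = True
        if not covered.all():
            raise ValueError("partitions do not cover all columns")

    # -- basic accessors -------------------------------------------------
    @property
    def width(self) -> int:
        return self.seqs.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return "".join(self.seqs[self.taxa.index(taxon)])

    def row_array(self, taxon: str) -> np.ndarray:
        return self.seqs[self.taxa.index(taxon)]

    def column(self, j: int) -> str:
        return "".join(self.seqs[:, j])

    def copy(self) -> "ConcatenatedMSA":
        return ConcatenatedMSA(
            list(self.taxa), self.seqs.copy(), dict(self.partitions), self.col_sources.copy()
        )

    # -- column subsetting ----------------------------------------------
    def take_columns(self, idx: Sequence[int]) -> "ConcatenatedMSA":
        """Keep the given columns (ascending order), re-indexing partitions."""
        idx = np.asarray(sorted(idx), dtype=np.int64)
        new_parts: dict[str, tuple[int, int]] = {}
        pos = 0
        for name, (start, end) in self.partitions.items():
            kept = int(((idx >= start) & (idx < end)).sum())
            new_parts[name] = (pos, pos + kept)
            pos += kept
        return ConcatenatedMSA(
            list(self.taxa), self.seqs[:, idx], new_parts, self.col_sources[idx]
        )

    def partition_view(self, protein: str) -> np.ndarray:
        start, end = self.partitions[protein]
        return self.seqs[:, start:end]

    # -- I/O --------------------------------------------------------------
    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, name in enumerate(self.taxa):
                fh.write(f">{name}\n{''.join(self.seqs[i])}\n")

    @classmethod
    def from_rows(
        cls,
        rows: Mapping[str, str],
        partitions: dict[str, tuple[int, int]] | None = None,
        protein: str | None = None,
    ) -> "ConcatenatedMSA":
        taxa = list(rows)
        seqs = np.array([list(rows[t]) for t in taxa], dtype="<U1")
        if partitions is None:
            name = protein if protein is not None else "all"
            partitions = {name: (0, seqs.shape[1] if taxa else 0)}
        return cls(taxa, seqs, partitions)

    @classmethod
    def from_fasta(cls, path, protein: str | None = None) -> "ConcatenatedMSA":
        from Bio import SeqIO

        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        widths = {len(s) for s in rows.values()}
        if len(widths) > 1:
            raise ValueError("FASTA records are not aligned (unequal lengths)")
        return cls.from_rows(rows, protein=protein)


def write_partition_tsv(msa: ConcatenatedMSA, path) -> None:
    """Partition map as TSV (protein, start, end; 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("protein\tstart\tend\n")
        for name, (start, end) in msa.partitions.items():
            fh.write(f"{name}\t{start}\t{end}\n")


def write_raxml_partitions(msa: ConcatenatedMSA, path, model: str = "PROTGAMMAGTR") -> None:
    """Partition map in RAxML-style text (1-based inclusive ranges)."""
    with open(path, "w") as fh:
        for name, (start, end) in msa.partitions.items():
            fh.write(f"{model}, {name} = {start + 1}-{end}\n")


def completeness_deficit(seq: Iterable[str]) -> int:
    """Number of absent characters ('-', 'X', '?') in a row."""
    return sum(1 for c in seq if c in ABSENT)


def select_representative(
    msa: ConcatenatedMSA, species_of: Mapping[str, str]
) -> ConcatenatedMSA:
    """Keep, for each species, the individual with the most complete row.

    Completeness is the count of non-absent characters; ties are broken by
    the lexicographically smallest individual id. The returned alignment is
    labeled by species name, in first-appearance order.
    """
    groups: dict[str, list[str]] = {}
    for taxon in msa.taxa:
        try:
            sp = species_of[taxon]
        except KeyError:
            raise ValueError(f"no species mapping for individual {taxon!r}") from None
        groups.setdefault(sp, []).append(taxon)
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty species group")
    chosen_rows = []
    species_names = []
    for sp, members in groups.items():
        best = min(members, key=lambda t: (completeness_deficit(msa.row(t)), t))
        chosen_rows.append(msa.row_array(best))
        species_names.append(sp)
    return ConcatenatedMSA(
        species_names, np.array(chosen_rows), dict(msa.partitions), msa.col_sources.copy()
    )


def strip_signal_peptides(
    msa: ConcatenatedMSA, signal_lengths: Mapping[str, int]
) -> ConcatenatedMSA:
    """Remove the leading signal-peptide columns of each protein partition.

    Signal peptides are N-terminal secretion tags that are never recovered
    in enamel paleoproteomics, so they are excluded before any analysis.
    """
    keep: list[int] = []
    for name, (start, end) in msa.partitions.items():
        cut = int(signal_lengths.get(name, 0))
        if cut < 0:
            raise ValueError(f"negative signal length for {name!r}")
        if cut >= end - start and end > start:
            raise ValueError(
                f"signal length {cut} for {name!r} not smaller than partition width {end - start}"
            )
        keep.extend(range(start + cut, end))
    return msa.take_columns(keep)


def concatenate(
    per_protein: Mapping[str, ConcatenatedMSA], fill_missing: bool = False
) -> ConcatenatedMSA:
    """Concatenate single-protein alignments into a supermatrix.

    All inputs must share the same taxon set unless ``fill_missing`` is
    true, in which case a taxon absent from a protein gets a full gap
    block there. The partition map records each protein's column interval
    in input order.
    """
    if not per_protein:
        raise ValueError("no alignments to concatenate")
    all_taxa: list[str] = []
    for name, msa in per_protein.items():
        if len(set(msa.taxa)) != len(msa.taxa):
            raise ValueError(f"duplicate taxon in protein {name!r}")
        for t in msa.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    if not fill_missing:
        for name, msa in per_protein.items():
            if set(msa.taxa) != set(all_taxa):
                missing = sorted(set(all_taxa) - set(msa.taxa))
                raise ValueError(
                    f"protein {name!r} is missing taxa {missing}; "
                    "pass fill_missing=True to pad with gaps"
                )
    blocks = []
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, msa in per_protein.items():
        block = np.full((len(all_taxa), msa.width), GAP, dtype="<U1")
        for i, t in enumerate(all_taxa):
            if t in msa.taxa:
                block[i] = msa.row_array(t)
        blocks.append(block)
        partitions[name] = (pos, pos + msa.width)
        pos += msa.width
    seqs = np.hstack(blocks) if blocks else np.zeros((len(all_taxa), 0), dtype="<U1")
    return ConcatenatedMSA(all_taxa, seqs, partitions)


def trim_columns(msa: ConcatenatedMSA, max_gap_fraction: float = 0.9) -> ConcatenatedMSA:
    """Drop columns whose gap ('-') fraction exceeds the threshold.

    A single-threshold stand-in for heuristic alignment trimmers; column
    provenance survives in ``col_sources``.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    gap_frac = (msa.seqs == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    return msa.take_columns(keep)


def fill_reference_gaps(msa: ConcatenatedMSA, reference_taxon: str) -> ConcatenatedMSA:
    """Replace gaps/masks in the reference row with the column consensus.

    Rate scoring uses the outgroup row as a complete reference sequence;
    columns where it has ``-`` or ``X`` get the modal residue among the
    informative characters of that column (alphabetically first on ties).
    Columns with no informative residue are left unchanged with a warning.
    """
    if reference_taxon not in msa.taxa:
        raise ValueError(f"reference taxon {reference_taxon!r} not in alignment")
    out = msa.copy()
    ridx = out.taxa.index(reference_taxon)
    uninformative = []
    for j in range(out.width):
        c = out.seqs[ridx, j]
        if c not in (GAP, MASK):
            continue
        counts = Counter(
            ch for ch in out.seqs[:, j] if ch not in ABSENT and ch != MISSING
        )
        if not counts:
            uninformative.append(j)
            continue
        best = min(counts, key=lambda a: (-counts[a], a))
        out.seqs[ridx, j] = best
    if uninformative:
        warnings.warn(
            f"{len(uninformative)} column(s) had no informative residue to fill "
            f"the reference row (first: {uninformative[0]})",
            stacklevel=2,
        )
    return out
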