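"""Coverage profiles and fragmentation-stage masks for ancient peptides.

Post-mortem sequence loss is modeled by removing alignment columns. The
model is coverage-informed: peptides recovered from dated samples are
mapped onto alignment columns, per-column recovery counts form a
:class:`CoverageProfile`, and a :class:`StageMask` derives from it either
by an age threshold (retain columns recovered from samples at least that
old) or by a target retained fraction (retain the best-covered columns).
Masks are applied globally (drop columns for everyone) or in case-study
mode (mark only selected taxa's residues as missing ``?``).

The four canonical stage labels — "100 ka", "1 to 2 Ma", "5 Ma",
"10 Ma" — carry default retained fractions 0.41 / 0.12 / 0.06 / 0.01 of
the concatenated width, calibrated to the 14-protein supermatrix lengths
9,557 → 3,884 / 1,139 / 593 / 98 the stages are named after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import GAP, MASK, MISSING
from .msa import ConcatenatedMSA

DEFAULT_STAGE_FRACTIONS: dict[str, float] = {
    "100 ka": 0.41,
    "1 to 2 Ma": 0.12,
    "5 Ma": 0.06,
    "10 Ma": 0.01,
}

CANONICAL_STAGES: tuple[str, ...] = tuple(DEFAULT_STAGE_FRACTIONS)


def retained_fraction(stage_width: int, full_width: int) -> float:
    """Fraction of the full concatenated width a reduced alignment keeps."""
    if full_width <= 0:
        raise ValueError("full width must be positive")
    if not (0 <= stage_width <= full_width):
        raise ValueError("stage width must be between 0 and the full width")
    return stage_width / full_width


@dataclass
class Peptide:
    sequence: str
    protein: str
    start: int | None = None  # 0-based source position, when known

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptides must be non-empty")


@dataclass
class AncientPeptideSet:
    """Peptides recovered from one dated sample."""

    sample_id: str
    age: float  # Ma
    peptides: list[Peptide]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("sample age must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "AncientPeptideSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "protein": str})
        if df.empty:
            raise ValueError("empty peptide table")
        sample = str(df["sample_id"].iloc[0])
        age = float(df["age"].iloc[0])
        peps = [Peptide(r.sequence, r.protein) for r in df.itertuples()]
        return cls(sample, age, peps)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tage\tprotein\tsequence\n")
            for p in self.peptides:
                fh.write(f"{self.sample_id}\t{self.age}\t{p.protein}\t{p.sequence}\n")


@dataclass
class MappedPeptides:
    """Peptides of one sample mapped to MSA columns."""

    sample_id: str
    age: float
    columns: list[tuple[Peptide, np.ndarray]]  # global MSA column indices
    discarded: list[tuple[Peptide, str]] = field(default_factory=list)
    errors: list[tuple[Peptide, str]] = field(default_factory=list)


def map_peptides_to_columns(
    peptide_set: AncientPeptideSet,
    msa: ConcatenatedMSA,
    anchor_taxon: str,
) -> MappedPeptides:
    """Locate each peptide on the anchor row and map it to MSA columns.

    A peptide must match exactly once as a substring of the anchor's
    ungapped sequence within its protein partition ('X' and '?' in the
    anchor match anything); the matched residue range is then mapped
    through the anchor's gap structure to alignment columns. Peptides
    with zero or multiple matches are discarded and reported.
    """
    if anchor_taxon not in msa.taxa:
        raise ValueError(f"anchor taxon {anchor_taxon!r} not in alignment")
    row = msa.row_array(anchor_taxon)
    mapped: list[tuple[Peptide, np.ndarray]] = []
    discarded: list[tuple[Peptide, str]] = []
    errors: list[tuple[Peptide, str]] = []
    # per-protein: ungapped anchor string and residue-index -> column map
    cache: dict[str, tuple[str, np.ndarray]] = {}
    for protein, (start, end) in msa.partitions.items():
        part = row[start:end]
        keep = part != GAP
        cols = np.flatnonzero(keep) + start
        cache[protein] = ("".join(part[keep]), cols)

    for pep in peptide_set.peptides:
        if pep.protein not in cache:
            errors.append((pep, f"unknown protein {pep.protein!r}"))
            continue
        anchor, cols = cache[pep.protein]
        m = len(pep.sequence)
        hits = []
        for i in range(len(anchor) - m + 1):
            window = anchor[i : i + m]
            if all(a == b or a in (MASK, MISSING) for a, b in zip(window, pep.sequence)):
                hits.append(i)
        if len(hits) != 1:
            reason = "no match" if not hits else f"{len(hits)} matches"
            discarded.append((pep, reason))
            continue
        i = hits[0]
        mapped.append((pep, cols[i : i + m].copy()))
    return MappedPeptides(peptide_set.sample_id, peptide_set.age, mapped, discarded, errors)


@dataclass
class CoverageProfile:
    """Per-protein per-column peptide recovery counts from dated samples."""

    counts: dict[str, np.ndarray]  # partition-local column counts
    max_age: dict[str, np.ndarray]  # oldest covering sample age (-inf if none)
    sample_ages: list[float]

    @property
    def total_width(self) -> int:
        return sum(len(v) for v in self.counts.values())


def build_coverage_profile(
    mapped_sets: Iterable[MappedPeptides], msa: ConcatenatedMSA
) -> CoverageProfile:
    """Aggregate mapped peptide sets into per-column recovery counts."""
    counts = {p: np.zeros(e - s, dtype=np.int64) for p, (s, e) in msa.partitions.items()}
    max_age = {p: np.full(e - s, -np.inf) for p, (s, e) in msa.partitions.items()}
    ages: list[float] = []
    starts = {p: s for p, (s, e) in msa.partitions.items()}
    for ms in mapped_sets:
        ages.append(ms.age)
        for pep, cols in ms.columns:
            local = cols - starts[pep.protein]
            counts[pep.protein][local] += 1
            np.maximum.at(max_age[pep.protein], local, ms.age)
    return CoverageProfile(counts, max_age, ages)


@dataclass
class StageDefinition:
    """One fragmentation stage: either an age threshold or a target fraction."""

    label: str
    age_threshold: float | None = None
    target_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.age_threshold is None) == (self.target_fraction is None):
            raise ValueError("give exactly one of age_threshold / target_fraction")
        if self.target_fraction is not None and not (0.0 <= self.target_fraction <= 1.0):
            raise ValueError("target fraction must be in [0, 1]")


def canonical_stage_definitions() -> list[StageDefinition]:
    return [
        StageDefinition(label, target_fraction=frac)
        for label, frac in DEFAULT_STAGE_FRACTIONS.items()
    ]


@dataclass
class StageMask:
    """Retained (partition-local) column indices per protein for one stage."""

    stage: str
    retained: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.retained = {
            p: np.asarray(sorted(v), dtype=np.int64) for p, v in self.retained.items()
        }

    def n_retained(self) -> int:
        return sum(len(v) for v in self.retained.values())

    def fraction(self, total_width: int) -> float:
        return self.n_retained() / total_width

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein\tretained_indices\n")
            for p, idx in self.retained.items():
                fh.write(f"{p}\t{','.join(map(str, idx))}\n")

    @classmethod
    def from_tsv(cls, path, stage: str = "custom") -> "StageMask":
        retained: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("protein"):
                raise ValueError("mask TSV must start with a 'protein' header line")
            for line in fh:
                if not line.strip():
                    continue
                protein, idx_str = line.rstrip("\n").split("\t")
                idx = [int(x) for x in idx_str.split(",") if x != ""]
                retained[protein] = np.asarray(idx, dtype=np.int64)
        return cls(stage, retained)


def build_stage_masks(
    profile: CoverageProfile,
    stage_definitions: Sequence[StageDefinition],
    force_empty: Iterable[str] = (),
) -> list[StageMask]:
    """Derive a retained-column mask per fragmentation stage.

    Age mode retains a column iff some sample of age >= threshold covered
    it. Fraction mode ranks all columns by recovery count (ties by
    protein order, then lower column index) and keeps the top fraction of
    the concatenated width, which makes fraction-based masks nested by
    construction. Proteins in ``force_empty`` retain nothing (e.g. TUFT1,
    for which no ancient peptides are known); a full-retention stage
    (target fraction 1.0) represents the intact alignment and keeps every
    column regardless.
    """
    force_empty = set(force_empty)
    proteins = list(profile.counts)
    total = profile.total_width
    # global ranking used by fraction mode
    ranked: list[tuple[int, int, int]] = []  # (-count, protein idx, col idx)
    for pi, p in enumerate(proteins):
        if p in force_empty:
            continue
        for j, c in enumerate(profile.counts[p]):
            ranked.append((-int(c), pi, j))
    ranked.sort()

    masks = []
    for sd in stage_definitions:
        retained = {p: np.zeros(0, dtype=np.int64) for p in proteins}
        if sd.age_threshold is not None:
            for p in proteins:
                if p in force_empty:
                    continue
                retained[p] = np.flatnonzero(profile.max_age[p] >= sd.age_threshold)
        elif sd.target_fraction == 1.0:
            retained = {
                p: np.arange(len(profile.counts[p]), dtype=np.int64) for p in proteins
            }
        else:
            n_keep = int(round(sd.target_fraction * total))
            chosen: dict[str, list[int]] = {p: [] for p in proteins}
            for negc, pi, j in ranked[:n_keep]:
                chosen[proteins[pi]].append(j)
            retained = {p: np.asarray(v, dtype=np.int64) for p, v in chosen.items()}
        masks.append(StageMask(sd.label, retained))
    return masks


def check_nestedness(masks: Sequence[StageMask], strict: bool = True) -> bool:
    """Verify masks listed youngest-first are nested (older ⊆ younger).

    Fraction-derived masks must nest (``strict=True`` raises on
    violation); age-derived masks may legitimately violate nesting — a
    young stage can include dentin collagens absent at older stages — so
    use ``strict=False`` to warn only.
    """
    ok = True
    for younger, older in zip(masks, masks[1:]):
        for p in older.retained:
            young = set(younger.retained.get(p, ()))
            if not set(older.retained[p]) <= young:
                ok = False
                msg = (
                    f"mask {older.stage!r} is not nested inside {younger.stage!r} "
                    f"for protein {p!r}"
                )
                if strict:
                    raise AssertionError(msg)
                warnings.warn(msg, stacklevel=2)
    return ok


def _mask_to_global_columns(msa: ConcatenatedMSA, mask: StageMask) -> np.ndarray:
    cols: list[int] = []
    for protein, idx in mask.retained.items():
        if protein not in msa.partitions:
            raise ValueError(f"mask protein {protein!r} not in alignment partitions")
        start, end = msa.partitions[protein]
        if len(idx) and (idx.min() < 0 or idx.max() >= end - start):
            raise ValueError(
                f"mask indices for {protein!r} outside partition width {end - start}"
            )
        cols.extend((idx + start).tolist())
    return np.asarray(sorted(cols), dtype=np.int64)


def apply_mask_global(msa: ConcatenatedMSA, mask: StageMask) -> ConcatenatedMSA:
    """Delete non-retained columns for all taxa (stage-wide fragmentation)."""
    return msa.take_columns(_mask_to_global_columns(msa, mask))


def apply_mask_case_study(
    msa: ConcatenatedMSA, mask: StageMask, target_taxa: Sequence[str]
) -> ConcatenatedMSA:
    """Fragment only the target taxa: their non-retained columns become '?'.

    The alignment width is unchanged and non-target rows are untouched,
    mimicking the placement of a fragmentary fossil among full-length
    reference sequences.
    """
    unknown = [t for t in target_taxa if t not in msa.taxa]
    if unknown:
        raise ValueError(f"unknown target taxa: {unknown}")
    keep_cols = set(_mask_to_global_columns(msa, mask).tolist())
    drop = np.array([j for j in range(msa.width) if j not in keep_cols], dtype=np.int64)
    out = msa.copy()
    for t in target_taxa:
        out.seqs[out.taxa.index(t), drop] = MISSING
    return out
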