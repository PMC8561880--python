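"""Readers, writers and coverage arithmetic for the pipeline's external formats.

All external coordinates follow their native dialects (1-based depth tables
and VCF, .fai-style contig tables); internally everything is 0-based
half-open.  Per-base depth tracks are always *densified*: positions absent
from a depth table become explicit zeros, because zero-coverage tracts in
one sex are precisely the signal the depth scan looks for.
"""

from __future__ import annotations

import enum
import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG_LEN = 3000


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"

    @property
    def other(self) -> "Sex":
        return Sex.FEMALE if self is Sex.MALE else Sex.MALE


class GenotypeState(enum.IntEnum):
    """Collapsed diploid genotype state: only het vs hom matters here."""

    HOM = 0
    HET = 1
    MISSING = 2


_SEX_TOKENS = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
}


@dataclass(frozen=True)
class SexedSample:
    sample_id: str
    sex: Sex


@dataclass(frozen=True)
class ContigTable:
    """Ordered contig (name, length) pairs, .fai style."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names in contig table")
        for name, length in self.entries:
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def __contains__(self, name: object) -> bool:
        return name in self.lengths

    def length(self, name: str) -> int:
        return self.lengths[name]

    def total_length(self) -> int:
        return sum(l for _, l in self.entries)

    def subset(self, names: Iterable[str]) -> "ContigTable":
        keep = set(names)
        return ContigTable(tuple((n, l) for n, l in self.entries if n in keep))


@dataclass
class DepthTrack:
    """Per-base read depth for one sample on one contig; zeros explicit."""

    sample_id: str
    contig: str
    depths: np.ndarray  # shape (contig_length,), non-negative ints


#: depth tracks for a whole cohort: sample_id -> contig -> per-base array
CohortDepths = dict[str, dict[str, np.ndarray]]


@dataclass
class GenotypeTable:
    """Variant-by-sample genotype states parsed from a multi-sample VCF."""

    contigs: np.ndarray  # str array, one per variant
    positions: np.ndarray  # 0-based ints, one per variant
    refs: list[str]
    alts: list[tuple[str, ...]]
    samples: list[str]
    states: np.ndarray  # int8 matrix (n_variants, n_samples) of GenotypeState

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    def subset_contigs(self, names: Iterable[str]) -> "GenotypeTable":
        keep = np.isin(self.contigs, list(names))
        idx = np.flatnonzero(keep)
        return GenotypeTable(
            contigs=self.contigs[keep],
            positions=self.positions[keep],
            refs=[self.refs[i] for i in idx],
            alts=[self.alts[i] for i in idx],
            samples=self.samples,
            states=self.states[keep],
        )


def read_sample_sheet(path: str | Path) -> list[SexedSample]:
    """Parse a two-column (sample_id, sex) sheet; sex tokens M/F/male/female."""
    cohort: list[SexedSample] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (sample_id, sex), got {line!r}"
                )
            sample_id, token = parts
            if sample_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample_id!r}")
            sex = _SEX_TOKENS.get(token.lower())
            if sex is None:
                raise ValueError(
                    f"{path}:{lineno}: unknown sex token {token!r} "
                    "(expected one of M, F, male, female)"
                )
            seen.add(sample_id)
            cohort.append(SexedSample(sample_id, sex))
    if not cohort:
        raise ValueError(f"{path}: no samples")
    return cohort


def validate_cohort(cohort: Sequence[SexedSample]) -> None:
    """Both sexes need >=2 samples so within-sex variances exist."""
    n_m = sum(1 for s in cohort if s.sex is Sex.MALE)
    n_f = len(cohort) - n_m
    if n_m < 2 or n_f < 2:
        raise ValueError(
            f"cohort needs at least 2 samples of each sex (got {n_m} male, {n_f} female)"
        )


def read_contig_table(path: str | Path) -> ContigTable:
    """Read a .fai-style table: name, length; further columns ignored."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least name and length")
            entries.append((parts[0], int(parts[1])))
    if not entries:
        raise ValueError(f"{path}: empty contig table")
    return ContigTable(tuple(entries))


def anchored_chromosome_table() -> ContigTable:
    """The 24 anchored trevally (Trevally_v1) chromosome-scale scaffolds."""
    ref = resources.files("sdrscan").joinpath("data/trevally_v1_chromosomes.fai")
    entries: list[tuple[str, int]] = []
    for line in ref.read_text().splitlines():
        name, length = line.split("\t")
        entries.append((name, int(length)))
    return ContigTable(tuple(entries))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_depth_table(
    path: str | Path, contigs: ContigTable, sample_id: str
) -> dict[str, DepthTrack]:
    """Read a 3-column samtools-depth-style TSV into dense per-base tracks.

    Positions absent from the table become depth 0; every contig in
    ``contigs`` yields a full-length track even if the file never mentions it.
    """
    lengths = contigs.lengths
    arrays = {name: np.zeros(length, dtype=np.int64) for name, length in contigs.entries}
    with _open_text(path) as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            header=None,
            names=["contig", "pos", "depth"],
            dtype={"contig": str, "pos": np.int64, "depth": np.int64},
        )
    if (df["depth"] < 0).any():
        bad = df.loc[df["depth"] < 0].iloc[0]
        raise ValueError(f"{path}: negative depth at {bad.contig}:{bad.pos}")
    for contig, sub in df.groupby("contig", sort=False):
        if contig not in lengths:
            # rows on contigs outside the (possibly length-filtered) table
            # are simply not part of the analysis
            logger.debug("%s: skipping %d rows on excluded contig %s",
                         path, len(sub), contig)
            continue
        pos = sub["pos"].to_numpy()
        if pos.min(initial=1) < 1 or pos.max(initial=1) > lengths[contig]:
            raise ValueError(
                f"{path}: position outside contig {contig} bounds (length {lengths[contig]})"
            )
        arrays[contig][pos - 1] = sub["depth"].to_numpy()
    return {
        name: DepthTrack(sample_id=sample_id, contig=name, depths=arr)
        for name, arr in arrays.items()
    }


def read_cohort_depths(
    depth_dir: str | Path, cohort: Sequence[SexedSample], contigs: ContigTable
) -> CohortDepths:
    """Read ``<sample_id>.depth.tsv[.gz]`` for every cohort member."""
    depth_dir = Path(depth_dir)
    out: CohortDepths = {}
    for sample in cohort:
        candidates = [
            depth_dir / f"{sample.sample_id}.depth.tsv",
            depth_dir / f"{sample.sample_id}.depth.tsv.gz",
        ]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(
                f"no depth table for sample {sample.sample_id!r} in {depth_dir}"
            )
        tracks = read_depth_table(path, contigs, sample.sample_id)
        out[sample.sample_id] = {c: t.depths for c, t in tracks.items()}
    return out


def _gt_to_state(alleles: Sequence[int]) -> int:
    if len(alleles) != 2:
        raise ValueError(f"non-diploid genotype with {len(alleles)} alleles")
    a, b = alleles
    if a < 0 or b < 0:
        return GenotypeState.MISSING
    return GenotypeState.HET if a != b else GenotypeState.HOM


def read_genotypes(
    path: str | Path,
    cohort: Sequence[SexedSample],
    contigs: ContigTable | None = None,
) -> GenotypeTable:
    """Parse a multi-sample VCF into HOM/HET/MISSING states.

    Phased separators are treated as unphased; multi-allelic genotypes with
    two distinct alleles (e.g. 1/2) are HET; a half-missing genotype is
    MISSING.  A VCF sample absent from the cohort sheet is a hard error.
    """
    cohort_ids = {s.sample_id for s in cohort}
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in cohort_ids]
    if unknown:
        raise ValueError(f"{path}: VCF samples not in sample sheet: {unknown}")
    lengths = contigs.lengths if contigs is not None else None

    contig_col: list[str] = []
    pos_col: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    rows: list[list[int]] = []
    for variant in vcf:
        pos0 = variant.POS - 1
        if lengths is not None:
            length = lengths.get(variant.CHROM)
            if length is not None and not (0 <= pos0 < length):
                raise ValueError(
                    f"{path}: variant {variant.CHROM}:{variant.POS} outside contig bounds"
                )
        row = [_gt_to_state(g[:-1]) for g in variant.genotypes]
        contig_col.append(variant.CHROM)
        pos_col.append(pos0)
        refs.append(variant.REF)
        alts.append(tuple(variant.ALT))
        rows.append(row)
    states = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeTable(
        contigs=np.array(contig_col, dtype=object),
        positions=np.array(pos_col, dtype=np.int64),
        refs=refs,
        alts=alts,
        samples=samples,
        states=states,
    )


def exclude_short_contigs(
    contigs: ContigTable,
    depths: CohortDepths | None = None,
    genotypes: GenotypeTable | None = None,
    min_len: int = DEFAULT_MIN_CONTIG_LEN,
) -> tuple[ContigTable, CohortDepths | None, GenotypeTable | None]:
    """Drop contigs strictly shorter than ``min_len`` (so 3000 bp survives 3000)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    keep = [n for n, l in contigs.entries if l >= min_len]
    if not keep:
        logger.warning("all %d contigs shorter than %d bp; nothing retained",
                       len(contigs.entries), min_len)
    filtered = contigs.subset(keep)
    keep_set = set(keep)
    depths_out = None
    if depths is not None:
        depths_out = {
            sid: {c: arr for c, arr in per.items() if c in keep_set}
            for sid, per in depths.items()
        }
    geno_out = genotypes.subset_contigs(keep_set) if genotypes is not None else None
    return filtered, depths_out, geno_out


def assembly_span(contigs: ContigTable, extra_unanchored: int = 0) -> tuple[int, int]:
    """Anchored span (sum of contig lengths) and grand total with unanchored bp."""
    if not contigs.entries:
        raise ValueError("empty contig table")
    if extra_unanchored < 0:
        raise ValueError("extra_unanchored must be >= 0")
    anchored = contigs.total_length()
    return anchored, anchored + extra_unanchored


def coverage_stats(
    total_input_bases: float,
    genome_size: float,
    mean_read_count: float,
    read_length: float,
    assembly_length: float,
) -> tuple[float, int]:
    """Fold coverage of input data and the rounded mean per-sample depth.

    fold_coverage = total_input_bases / genome_size, reported to one decimal;
    mean depth = round(mean_read_count * read_length / assembly_length).
    """
    if genome_size <= 0 or assembly_length <= 0:
        raise ValueError("genome_size and assembly_length must be positive")
    if min(total_input_bases, mean_read_count, read_length) <= 0:
        raise ValueError("all inputs must be positive")
    fold = round(total_input_bases / genome_size, 1)
    mean_depth = round(mean_read_count * read_length / assembly_length)
    return fold, int(mean_depth)
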