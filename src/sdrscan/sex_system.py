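"""Merge depth and variant evidence into regions, classify XY/ZW/spurious,
and orchestrate the whole scan end-to-end.

The decision logic encodes how a heterogametic system looks against a
reference that contains the sex-limited chromosome's sequence: in an XY
system, males carry extra (Y-derived) sequence — females show zero or
strongly reduced read depth over it — and the diverged interval is
heterozygous in all males while homozygous in all females.  A ZW system is
the mirror image.  Het-state association *without* co-located depth
evidence is the signature of a false discovery and is labelled spurious.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import depth_scan, io_formats, variant_scan
from .depth_scan import ZeroDepthTract
from .io_formats import ContigTable, Sex, SexedSample
from .variant_scan import Direction

logger = logging.getLogger(__name__)


class Classification:
    XY_LINKED = "XY_LINKED"
    ZW_LINKED = "ZW_LINKED"
    SPURIOUS = "SPURIOUS"
    AMBIGUOUS = "AMBIGUOUS"


class System:
    XY = "XY"
    ZW = "ZW"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class PipelineConfig:
    """All numeric knobs of the scan, with the study's defaults."""

    bin_width: int = 1000
    density_window: int = 5000
    density_min_count: int = 10
    neglogp_threshold: float = 2.0
    min_contig_len: int = 3000
    neglogp_cap: float = 300.0
    p_floor: float = 1e-300
    merge_gap: int = 1000
    zero_depth_max: int = 0
    min_tract_len: int = 1000
    colocalization_slop: int = 5000
    #: a depth-deficit window only counts as co-located depth evidence if the
    #: deficit sex's mean is below this fraction of the other sex's mean —
    #: consistent with loss of at least one chromosome copy (hemizygous ~0.5)
    deficit_ratio: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_width", "density_window", "min_contig_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("density_min_count", "neglogp_threshold", "merge_gap",
                     "zero_depth_max", "min_tract_len", "colocalization_slop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value config; unknown keys are a hard error."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                caster = float if "float" in str(fields[key]) else int
                kwargs[key] = caster(value)
        return cls(**kwargs)


@dataclass
class RegionEvidence:
    variant_direction: str = Direction.NONE.value
    has_density_signal: bool = False
    female_zero_tract_overlap: bool = False
    male_zero_tract_overlap: bool = False
    depth_window_overlap: bool = False
    female_deficit_window: bool = False
    male_deficit_window: bool = False
    n_flagged_variants: int = 0
    max_neg_log10_p: float = 0.0


@dataclass
class RegionCall:
    contig: str
    start: int
    end: int
    from_density: bool
    from_depth: bool
    evidence: RegionEvidence
    classification: str


@dataclass
class SexSystemVerdict:
    system: str
    supporting_regions: list[RegionCall]
    rationale: str


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: list[SexedSample]
    contigs: ContigTable
    window_stats: pd.DataFrame
    retained_windows: pd.DataFrame
    associations: pd.DataFrame
    flagged: pd.DataFrame
    density: pd.DataFrame
    female_tracts: list[ZeroDepthTract]
    male_tracts: list[ZeroDepthTract]
    regions: list[RegionCall]
    verdict: SexSystemVerdict


def _intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def merge_candidate_regions(
    density: pd.DataFrame,
    retained_windows: pd.DataFrame,
    merge_gap: int = 1000,
) -> list[tuple[str, int, int, bool, bool]]:
    """Union density windows and retained depth windows per contig, merging
    intervals separated by at most ``merge_gap`` bp.

    Returns (contig, start, end, from_density, from_depth) tuples sorted by
    contig then start.
    """
    raw: dict[str, list[tuple[int, int, bool, bool]]] = {}
    for _, row in density.iterrows():
        raw.setdefault(str(row["contig"]), []).append(
            (int(row["start"]), int(row["end"]), True, False)
        )
    for _, row in retained_windows.iterrows():
        raw.setdefault(str(row["contig"]), []).append(
            (int(row["start"]), int(row["end"]), False, True)
        )
    merged: list[tuple[str, int, int, bool, bool]] = []
    for contig in sorted(raw):
        intervals = sorted(raw[contig])
        cur_s, cur_e, cur_d, cur_w = intervals[0]
        for s, e, d, w in intervals[1:]:
            if s <= cur_e + merge_gap:
                cur_e = max(cur_e, e)
                cur_d |= d
                cur_w |= w
            else:
                merged.append((contig, cur_s, cur_e, cur_d, cur_w))
                cur_s, cur_e, cur_d, cur_w = s, e, d, w
        merged.append((contig, cur_s, cur_e, cur_d, cur_w))
    return merged


def classify_region(
    region: tuple[str, int, int, bool, bool],
    female_tracts: Sequence[ZeroDepthTract],
    male_tracts: Sequence[ZeroDepthTract],
    flagged: pd.DataFrame,
    retained_windows: pd.DataFrame,
    config: PipelineConfig,
) -> RegionCall:
    """Apply the XY/ZW/spurious rule table to one merged candidate region.

    Co-location means overlap with the region expanded by
    ``colocalization_slop`` on each side.  Male-het variants plus a
    co-located female depth deficit (zero tract, or retained windows with
    female mean below ``deficit_ratio`` x male mean) give XY_LINKED;
    the mirror gives ZW_LINKED; het association without co-located depth
    evidence is SPURIOUS; everything else is AMBIGUOUS.
    """
    contig, start, end, from_density, from_depth = region
    slop = config.colocalization_slop
    lo, hi = max(0, start - slop), end + slop
    ev = RegionEvidence(has_density_signal=from_density)

    in_region = flagged[
        (flagged["contig"] == contig)
        & (flagged["pos"] >= lo)
        & (flagged["pos"] < hi)
    ]
    ev.n_flagged_variants = len(in_region)
    dirs = set(in_region["direction"]) - {Direction.NONE.value}
    if len(dirs) == 1:
        ev.variant_direction = dirs.pop()
    elif len(dirs) > 1:
        ev.variant_direction = Direction.MIXED.value
    if len(in_region):
        ev.max_neg_log10_p = float(in_region["neg_log10_p"].max())

    ev.female_zero_tract_overlap = any(
        t.contig == contig and _intervals_overlap(t.start, t.end, lo, hi)
        for t in female_tracts
    )
    ev.male_zero_tract_overlap = any(
        t.contig == contig and _intervals_overlap(t.start, t.end, lo, hi)
        for t in male_tracts
    )

    windows = retained_windows[
        (retained_windows["contig"] == contig)
        & (retained_windows["start"] < hi)
        & (retained_windows["end"] > lo)
    ]
    if len(windows):
        ev.depth_window_overlap = True
        ev.max_neg_log10_p = max(ev.max_neg_log10_p, float(windows["neg_log10_p"].max()))
        ratio = config.deficit_ratio
        ev.female_deficit_window = bool(
            (windows["female_mean"] < ratio * windows["male_mean"]).any()
        )
        ev.male_deficit_window = bool(
            (windows["male_mean"] < ratio * windows["female_mean"]).any()
        )

    female_deficit = ev.female_zero_tract_overlap or ev.female_deficit_window
    male_deficit = ev.male_zero_tract_overlap or ev.male_deficit_window
    if ev.variant_direction == Direction.MALE_HET.value and female_deficit:
        classification = Classification.XY_LINKED
        if ev.male_zero_tract_overlap:
            logger.warning(
                "%s:%d-%d: XY-linked call where some or all males also lack "
                "coverage — possible repeat-confounded scaffold", contig, start, end,
            )
    elif ev.variant_direction == Direction.FEMALE_HET.value and male_deficit:
        classification = Classification.ZW_LINKED
        if ev.female_zero_tract_overlap:
            logger.warning(
                "%s:%d-%d: ZW-linked call where some or all females also lack "
                "coverage — possible repeat-confounded scaffold", contig, start, end,
            )
    elif ev.variant_direction in (Direction.MALE_HET.value, Direction.FEMALE_HET.value):
        classification = Classification.SPURIOUS
    else:
        classification = Classification.AMBIGUOUS
    return RegionCall(contig, start, end, from_density, from_depth, ev, classification)


def infer_sex_system(regions: Sequence[RegionCall]) -> SexSystemVerdict:
    """XY iff at least one XY_LINKED region and no ZW_LINKED, and vice versa;
    anything else (including conflict) is UNDETERMINED."""
    xy = [r for r in regions if r.classification == Classification.XY_LINKED]
    zw = [r for r in regions if r.classification == Classification.ZW_LINKED]
    if xy and not zw:
        contigs = sorted({r.contig for r in xy})
        return SexSystemVerdict(
            System.XY, xy,
            "male-heterozygous variants with co-located female depth deficit on "
            + ", ".join(contigs),
        )
    if zw and not xy:
        contigs = sorted({r.contig for r in zw})
        return SexSystemVerdict(
            System.ZW, zw,
            "female-heterozygous variants with co-located male depth deficit on "
            + ", ".join(contigs),
        )
    if xy and zw:
        return SexSystemVerdict(
            System.UNDETERMINED, [],
            "conflicting XY-linked and ZW-linked regions",
        )
    return SexSystemVerdict(System.UNDETERMINED, [], "no sex-linked region detected")


# ---------------------------------------------------------------------------
# orchestration

_FLOAT_FMT = "%.6g"


def _write_bed(path: Path, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(
    sample_sheet: str | Path,
    depth_dir: str | Path,
    vcf: str | Path,
    contig_table: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full scan: contig filtering, depth scan, variant scan,
    region merging, classification and the sex-system verdict.

    With ``out_dir`` set, writes per-window and per-variant TSVs, BED files
    of retained windows, zero-depth tracts, density windows and classified
    regions, a verdict file and a run log.  Partial outputs are removed on
    failure; identical inputs, seed and config give byte-identical outputs.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        cohort = io_formats.read_sample_sheet(sample_sheet)
        io_formats.validate_cohort(cohort)
        contigs = io_formats.read_contig_table(contig_table)
        contigs, _, _ = io_formats.exclude_short_contigs(
            contigs, min_len=config.min_contig_len
        )
        depths = io_formats.read_cohort_depths(depth_dir, cohort, contigs)
        genotypes = io_formats.read_genotypes(vcf, cohort, None)
        genotypes = genotypes.subset_contigs(contigs.names)

        binned = depth_scan.bin_depths(depths, contigs, config.bin_width)
        window_stats = depth_scan.welch_window_tests(
            binned, cohort, p_floor=config.p_floor, neglogp_cap=config.neglogp_cap
        )
        retained = depth_scan.filter_depth_windows(window_stats, config.neglogp_threshold)
        female_tracts = depth_scan.zero_depth_tracts(
            depths, cohort, Sex.FEMALE, contigs,
            max_allowed_depth=config.zero_depth_max,
            min_tract_len=config.min_tract_len,
        )
        male_tracts = depth_scan.zero_depth_tracts(
            depths, cohort, Sex.MALE, contigs,
            max_allowed_depth=config.zero_depth_max,
            min_tract_len=config.min_tract_len,
        )

        associations = variant_scan.associate_variants(
            genotypes, cohort, neglogp_cap=config.neglogp_cap
        )
        flagged = variant_scan.flag_fully_associated(associations)
        density = variant_scan.density_windows(
            flagged, contigs, config.density_window, config.density_min_count
        )

        raw_regions = merge_candidate_regions(density, retained, config.merge_gap)
        regions = [
            classify_region(r, female_tracts, male_tracts, flagged, retained, config)
            for r in raw_regions
        ]
        verdict = infer_sex_system(regions)
        result = PipelineResult(
            config=config, cohort=cohort, contigs=contigs,
            window_stats=window_stats, retained_windows=retained,
            associations=associations, flagged=flagged, density=density,
            female_tracts=female_tracts, male_tracts=male_tracts,
            regions=regions, verdict=verdict,
        )
        if out is not None:
            _write_outputs(result, out)
        return result
    except Exception:
        if out is not None and out.exists():
            shutil.rmtree(out, ignore_errors=True)
        raise


def _write_outputs(result: PipelineResult, out: Path) -> None:
    cfg = result.config
    result.window_stats.to_csv(
        out / "windows.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    result.associations.to_csv(
        out / "variants.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    _write_bed(
        out / "windows_retained.bed",
        [
            (r.contig, r.start, r.end, "depth_window",
             min(int(round(r.neg_log10_p)), 1000), ".")
            for r in result.retained_windows.itertuples()
        ],
    )
    _write_bed(
        out / "density_windows.bed",
        [
            (r.contig, r.start, r.end, r.direction, int(r.count), ".")
            for r in result.density.itertuples()
        ],
    )
    _write_bed(
        out / "zero_depth_tracts.bed",
        [
            (t.contig, t.start, t.end, f"{t.sex.value}_ZERO", 0, ".")
            for t in sorted(
                result.female_tracts + result.male_tracts,
                key=lambda t: (t.contig, t.start, t.sex.value),
            )
        ],
    )
    _write_bed(
        out / "regions.bed",
        [
            (r.contig, r.start, r.end, r.classification,
             min(int(round(r.evidence.max_neg_log10_p)), 1000), ".")
            for r in result.regions
        ],
    )
    with open(out / "verdict.txt", "w") as fh:
        fh.write(f"system\t{result.verdict.system}\n")
        fh.write(f"rationale\t{result.verdict.rationale}\n")
        for r in result.verdict.supporting_regions:
            fh.write(f"region\t{r.contig}:{r.start}-{r.end}\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("sdrscan run\n")
        for f in dataclasses.fields(cfg):
            fh.write(f"config.{f.name}={getattr(cfg, f.name)}\n")
        fh.write(f"cohort_size={len(result.cohort)}\n")
        fh.write(f"contigs_retained={len(result.contigs.entries)}\n")
        fh.write(f"verdict={result.verdict.system}\n")
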