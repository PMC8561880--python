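"""Synthetic sexed-cohort generator with planted sex-determination architecture.

The generator emulates the summary files a resequencing study produces —
per-sample per-base depth tables, a multi-sample VCF, a sample sheet and a
contig table — without simulating reads: depth is drawn per base from a
Poisson (or negative-binomial) model whose mean is scaled inside planted
features, and genotypes are drawn under Hardy-Weinberg at background sites
and by sex-linkage rules inside features.  Default cohort and depth match
the study conditions this package targets: 7 males + 6 females at 13x mean
depth.

Planted feature kinds
---------------------
XY_SDR
    Male-limited sequence against a Y-containing reference: female depth
    scaled to ~0x, male depth to ~0.5x (hemizygous), male-heterozygous /
    female-homozygous variants at the sex-linked density.
ZW_SDR
    Mirror image.
SPURIOUS_HET
    Sex-biased heterozygosity with *no* depth signal (both sexes 1.0x) —
    the false-discovery signature.
REPEAT_CONFOUND
    Male-het variants over a collapsed repeat: all females at ~0x and a
    random subset of males also at ~0x.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import Sex

#: fully-associated variants per bp inside an SDR; 25 variants over ~6 kb
DEFAULT_SDR_VARIANT_DENSITY = 25 / 6000
#: cohort-wide segregating variants per bp of background sequence
#: (~16.58 M variants over a ~579.4 Mb genome)
DEFAULT_BACKGROUND_RATE = 0.0286


class FeatureKind(enum.Enum):
    XY_SDR = "XY_SDR"
    ZW_SDR = "ZW_SDR"
    SPURIOUS_HET = "SPURIOUS_HET"
    REPEAT_CONFOUND = "REPEAT_CONFOUND"


@dataclass(frozen=True)
class PlantedFeature:
    kind: FeatureKind
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    variant_density: float = DEFAULT_SDR_VARIANT_DENSITY
    het_depth_factor: float = 0.5  # heterogametic sex inside the feature
    hom_depth_factor: float = 0.0  # homogametic sex inside the feature
    het_sex: Sex = Sex.FEMALE  # which sex is heterozygous (SPURIOUS_HET only)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature interval [{self.start},{self.end})")


@dataclass
class SimulationConfig:
    n_males: int = 7
    n_females: int = 6
    contigs: tuple[tuple[str, int], ...] = (("contig_1", 30_000),)
    mean_depth: float = 13.0
    depth_model: str = "poisson"  # or "negbin"
    negbin_dispersion: float = 5.0  # gamma shape; larger = closer to Poisson
    background_variant_rate: float = DEFAULT_BACKGROUND_RATE
    features: tuple[PlantedFeature, ...] = ()
    genotype_error: float = 0.01  # symmetric HET<->HOM state-flip probability
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_variant_rate", "genotype_error", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        lengths = dict(self.contigs)
        if len(lengths) != len(self.contigs):
            raise ValueError("duplicate contig names")
        for feat in self.features:
            if feat.contig not in lengths:
                raise ValueError(f"feature on unknown contig {feat.contig!r}")
            if feat.end > lengths[feat.contig]:
                raise ValueError(f"feature [{feat.start},{feat.end}) exceeds contig")
        by_contig: dict[str, list[PlantedFeature]] = {}
        for feat in self.features:
            by_contig.setdefault(feat.contig, []).append(feat)
        for feats in by_contig.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping planted features on {a.contig}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )


@dataclass
class SimulatedCohort:
    out_dir: Path
    sample_sheet: Path
    contig_table: Path
    depth_dir: Path
    vcf: Path
    truth_bed: Path
    config: SimulationConfig


# genotype string codes used while building the VCF
_GT_HOM_REF, _GT_HET, _GT_HOM_ALT, _GT_MISS = 0, 1, 2, 3
_GT_STR = {_GT_HOM_REF: "0/0", _GT_HET: "0/1", _GT_HOM_ALT: "1/1", _GT_MISS: "./."}


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    males = [f"M{i + 1:02d}" for i in range(config.n_males)]
    females = [f"F{i + 1:02d}" for i in range(config.n_females)]
    return males, females


def _depth_factors(
    config: SimulationConfig, contig: str, length: int,
    males: list[str], females: list[str], rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-sample multiplicative depth factor along one contig."""
    factors = {sid: np.ones(length) for sid in males + females}
    for feat in config.features:
        if feat.contig != contig:
            continue
        sl = slice(feat.start, feat.end)
        if feat.kind is FeatureKind.XY_SDR:
            for sid in males:
                factors[sid][sl] = feat.het_depth_factor
            for sid in females:
                factors[sid][sl] = feat.hom_depth_factor
        elif feat.kind is FeatureKind.ZW_SDR:
            for sid in females:
                factors[sid][sl] = feat.het_depth_factor
            for sid in males:
                factors[sid][sl] = feat.hom_depth_factor
        elif feat.kind is FeatureKind.REPEAT_CONFOUND:
            for sid in females:
                factors[sid][sl] = 0.0
            n_drop = max(1, len(males) // 2)
            dropped = rng.choice(males, size=n_drop, replace=False)
            for sid in dropped:
                factors[sid][sl] = 0.0
        # SPURIOUS_HET: no depth signal by definition
    return factors


def _draw_depth(
    lam: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.depth_model == "poisson":
        return rng.poisson(lam)
    if config.depth_model == "negbin":
        shape = config.negbin_dispersion
        mixed = np.where(lam > 0, rng.gamma(shape, 1.0, size=lam.shape) * lam / shape, 0.0)
        return rng.poisson(mixed)
    raise ValueError(f"unknown depth_model {config.depth_model!r}")


def _feature_variants(
    feat: PlantedFeature, n_males: int, n_females: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and truth genotype matrix (variant x sample) for one feature."""
    span = feat.end - feat.start
    n = rng.binomial(span, feat.variant_density)
    pos = np.sort(rng.choice(span, size=n, replace=False)) + feat.start
    if feat.kind in (FeatureKind.XY_SDR, FeatureKind.REPEAT_CONFOUND):
        het_male = True
    elif feat.kind is FeatureKind.ZW_SDR:
        het_male = False
    else:
        het_male = feat.het_sex is Sex.MALE
    male_gt = _GT_HET if het_male else _GT_HOM_REF
    female_gt = _GT_HOM_REF if het_male else _GT_HET
    gts = np.empty((n, n_males + n_females), dtype=np.int8)
    gts[:, :n_males] = male_gt
    gts[:, n_males:] = female_gt
    return pos, gts


def _background_variants(
    contig_len: int, occupied: np.ndarray, n_samples: int,
    rate: float, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotypes at sex-independent background sites outside features."""
    free = np.flatnonzero(~occupied)
    n = min(rng.binomial(contig_len, rate), len(free))
    pos = np.sort(rng.choice(free, size=n, replace=False))
    q = rng.uniform(0.05, 0.95, size=n)  # alt allele frequency per site
    p_hom_ref = (1 - q) ** 2
    p_het = 2 * q * (1 - q)
    u = rng.uniform(size=(n, n_samples))
    gts = np.where(
        u < p_hom_ref[:, None], _GT_HOM_REF,
        np.where(u < (p_hom_ref + p_het)[:, None], _GT_HET, _GT_HOM_ALT),
    ).astype(np.int8)
    return pos, gts


def _perturb_genotypes(
    gts: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply symmetric HET<->HOM state flips (rate epsilon), then missingness."""
    out = gts.copy()
    flip = rng.uniform(size=out.shape) < config.genotype_error
    is_het = out == _GT_HET
    het_to = np.where(rng.uniform(size=out.shape) < 0.5, _GT_HOM_REF, _GT_HOM_ALT)
    out[flip & is_het] = het_to[flip & is_het]
    out[flip & ~is_het] = _GT_HET
    miss = rng.uniform(size=out.shape) < config.missing_rate
    out[miss] = _GT_MISS
    return out


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Write a complete synthetic cohort under ``out_dir``.

    Produces ``samples.tsv``, ``contigs.fai``, ``depth/<sample>.depth.tsv``
    (zero-depth rows omitted, exercising the reader's densification),
    ``variants.vcf`` (v4.2, GT-only FORMAT) and ``truth.bed`` listing every
    planted feature.  The same config (including seed) gives byte-identical
    files.
    """
    out = Path(out_dir)
    depth_dir = out / "depth"
    depth_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    males, females = _sample_ids(config)
    samples = males + females

    sheet = out / "samples.tsv"
    with open(sheet, "w") as fh:
        for sid in males:
            fh.write(f"{sid}\tM\n")
        for sid in females:
            fh.write(f"{sid}\tF\n")
    fai = out / "contigs.fai"
    with open(fai, "w") as fh:
        for name, length in config.contigs:
            fh.write(f"{name}\t{length}\n")

    # depth: one factor map per contig, Poisson/negbin draws in fixed order
    per_sample_frames: dict[str, list[pd.DataFrame]] = {sid: [] for sid in samples}
    for contig, length in config.contigs:
        factors = _depth_factors(config, contig, length, males, females, rng)
        for sid in samples:
            depth = _draw_depth(config.mean_depth * factors[sid], config, rng)
            nz = np.flatnonzero(depth)
            per_sample_frames[sid].append(
                pd.DataFrame({"contig": contig, "pos": nz + 1, "depth": depth[nz]})
            )
    for sid in samples:
        df = pd.concat(per_sample_frames[sid], ignore_index=True)
        df.to_csv(depth_dir / f"{sid}.depth.tsv", sep="\t", header=False, index=False)

    # variants: planted feature sites first, HWE background on the remainder
    vcf_path = out / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdrscan-synthetic-cohort\n")
        for name, length in config.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for contig, length in config.contigs:
            occupied = np.zeros(length, dtype=bool)
            pos_list: list[np.ndarray] = []
            gt_list: list[np.ndarray] = []
            for feat in config.features:
                if feat.contig != contig:
                    continue
                occupied[feat.start:feat.end] = True
                pos, gts = _feature_variants(
                    feat, config.n_males, config.n_females, rng
                )
                pos_list.append(pos)
                gt_list.append(gts)
            bg_pos, bg_gts = _background_variants(
                length, occupied, len(samples), config.background_variant_rate, rng
            )
            pos_list.append(bg_pos)
            gt_list.append(bg_gts)
            all_pos = np.concatenate(pos_list)
            all_gts = np.vstack(gt_list) if gt_list else np.empty((0, len(samples)))
            order = np.argsort(all_pos, kind="stable")
            all_pos = all_pos[order]
            all_gts = _perturb_genotypes(all_gts[order], config, rng)
            for pos0, row in zip(all_pos, all_gts):
                gt_str = "\t".join(_GT_STR[int(g)] for g in row)
                fh.write(f"{contig}\t{pos0 + 1}\t.\tA\tT\t.\t.\t.\tGT\t{gt_str}\n")

    truth = out / "truth.bed"
    with open(truth, "w") as fh:
        for feat in sorted(config.features, key=lambda f: (f.contig, f.start)):
            fh.write(f"{feat.contig}\t{feat.start}\t{feat.end}\t{feat.kind.value}\n")

    return SimulatedCohort(
        out_dir=out, sample_sheet=sheet, contig_table=fai,
        depth_dir=depth_dir, vcf=vcf_path, truth_bed=truth, config=config,
    )


def make_fixture(name: str, seed: int = 0) -> SimulationConfig:
    """Pinned study-scale test configurations.

    ``xy_small``: three 30 kb contigs, a 6 kb XY SDR at the proximal end of
    the first (mirroring a ~6 kb region at the start of a sex chromosome)
    plus a 5.5 kb spurious female-het region on the second.  ``zw_small`` is
    the mirror image; ``null_small`` has no planted features; ``confounded``
    adds a short repeat-confounded scaffold and a sub-3 kb contig that the
    length filter must drop.
    """
    contigs = (("contig_1", 30_000), ("contig_2", 30_000), ("contig_3", 30_000))
    if name == "xy_small":
        features: tuple[PlantedFeature, ...] = (
            PlantedFeature(FeatureKind.XY_SDR, "contig_1", 0, 6000),
            PlantedFeature(FeatureKind.SPURIOUS_HET, "contig_2", 10_000, 15_500,
                           het_sex=Sex.FEMALE),
        )
    elif name == "zw_small":
        features = (
            PlantedFeature(FeatureKind.ZW_SDR, "contig_1", 0, 6000),
            PlantedFeature(FeatureKind.SPURIOUS_HET, "contig_2", 10_000, 15_500,
                           het_sex=Sex.MALE),
        )
    elif name == "null_small":
        features = ()
    elif name == "confounded":
        contigs = contigs + (("scaffold_rep", 4013), ("contig_short", 2500))
        features = (
            PlantedFeature(FeatureKind.XY_SDR, "contig_1", 0, 6000),
            PlantedFeature(FeatureKind.SPURIOUS_HET, "contig_2", 10_000, 15_500,
                           het_sex=Sex.FEMALE),
            PlantedFeature(FeatureKind.REPEAT_CONFOUND, "scaffold_rep", 0, 4000,
                           variant_density=0.006),
        )
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return SimulationConfig(contigs=contigs, features=features, seed=seed)
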