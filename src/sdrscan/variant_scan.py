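"""Per-variant genotype-state association with sex, and density windows.

A variant whose genotype state (heterozygous vs homozygous) tracks sex is
the signature of sequence divergence between sex chromosomes: the
heterogametic sex (XY males, or ZW females) is heterozygous across the
diverged interval while the homogametic sex is homozygous.  Association is
scored with a two-sided Fisher exact test on the 2x2 sex-by-state table;
variants *entirely* associated with sex (all of one sex het, all of the
other hom, nobody missing) are flagged, and 5 kb tiles holding more than a
minimum count of flagged variants become density windows.
"""

from __future__ import annotations

import enum
import logging
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import ContigTable, GenotypeState, GenotypeTable, Sex, SexedSample

logger = logging.getLogger(__name__)

DEFAULT_DENSITY_WINDOW = 5000
DEFAULT_DENSITY_MIN_COUNT = 10

#: relative tolerance when comparing table probabilities to the observed
#: point probability, matching R's fisher.test two-sided rule
_REL_TOL = 1e-7

VARIANT_COLUMNS = [
    "contig", "pos", "het_males", "hom_males", "het_females", "hom_females",
    "n_missing", "p", "neg_log10_p", "fully_associated", "direction",
]


class Direction(enum.Enum):
    MALE_HET = "MALE_HET"
    FEMALE_HET = "FEMALE_HET"
    NONE = "NONE"
    MIXED = "MIXED"


@lru_cache(maxsize=100_000)
def _fisher_p(het_m: int, hom_m: int, het_f: int, hom_f: int) -> float:
    """Two-sided exact p for the 2x2 table by hypergeometric enumeration.

    With row margins (males, females) and column margins (het, hom) fixed,
    the two-sided p-value is the total probability of all tables whose point
    probability does not exceed that of the observed table.
    """
    n_m = het_m + hom_m
    n_f = het_f + hom_f
    n = n_m + n_f
    k = het_m + het_f  # total het
    lo = max(0, k - n_f)
    hi = min(n_m, k)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, k, n_m)
    observed = pmf[het_m - lo]
    p = float(pmf[pmf <= observed * (1 + _REL_TOL)].sum())
    return min(p, 1.0)


def fisher_sex_state_test(
    states: Sequence[int] | np.ndarray, cohort: Sequence[SexedSample]
) -> tuple[float, Direction]:
    """Fisher exact test of sex vs genotype state for one variant.

    MISSING samples are dropped.  Direction is the sex with the higher
    heterozygous fraction among genotyped samples (NONE on a tie).  A sex
    with no genotyped samples at all is a hard error; callers scanning many
    variants skip such records instead.
    """
    states = np.asarray(states)
    if len(states) != len(cohort):
        raise ValueError("one state per cohort sample required")
    is_male = np.array([s.sex is Sex.MALE for s in cohort])
    ok = states != GenotypeState.MISSING
    het = states == GenotypeState.HET
    het_m = int(np.sum(ok & is_male & het))
    hom_m = int(np.sum(ok & is_male & ~het))
    het_f = int(np.sum(ok & ~is_male & het))
    hom_f = int(np.sum(ok & ~is_male & ~het))
    if het_m + hom_m == 0 or het_f + hom_f == 0:
        raise ValueError("a sex is entirely missing for this variant")
    p = _fisher_p(het_m, hom_m, het_f, hom_f)
    frac_m = het_m / (het_m + hom_m)
    frac_f = het_f / (het_f + hom_f)
    if frac_m > frac_f:
        direction = Direction.MALE_HET
    elif frac_f > frac_m:
        direction = Direction.FEMALE_HET
    else:
        direction = Direction.NONE
    return p, direction


def associate_variants(
    genotypes: GenotypeTable,
    cohort: Sequence[SexedSample],
    neglogp_cap: float = 300.0,
) -> pd.DataFrame:
    """Score every variant; one row per variant with counts, p and flags.

    Variants where one sex has no genotyped sample are skipped with a logged
    count.  ``fully_associated`` applies the cohort-complete rule: every
    member of the cohort genotyped, one sex all HET, the other all HOM.
    """
    sex_by_id = {s.sample_id: s.sex for s in cohort}
    missing_samples = [s for s in genotypes.samples if s not in sex_by_id]
    if missing_samples:
        raise ValueError(f"VCF samples without sex labels: {missing_samples}")
    is_male = np.array([sex_by_id[s] is Sex.MALE for s in genotypes.samples])
    n_m = int(is_male.sum())
    n_f = int((~is_male).sum())

    st = genotypes.states
    ok = st != GenotypeState.MISSING
    het = st == GenotypeState.HET
    het_m = np.sum(ok & het & is_male, axis=1)
    hom_m = np.sum(ok & ~het & is_male, axis=1)
    het_f = np.sum(ok & het & ~is_male, axis=1)
    hom_f = np.sum(ok & ~het & ~is_male, axis=1)
    n_missing = np.sum(~ok, axis=1)

    usable = (het_m + hom_m > 0) & (het_f + hom_f > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("skipped %d variants with a sex entirely missing", n_skipped)

    idx = np.flatnonzero(usable)
    p = np.array([_fisher_p(int(het_m[i]), int(hom_m[i]), int(het_f[i]), int(hom_f[i]))
                  for i in idx])
    with np.errstate(divide="ignore"):
        neglogp = np.minimum(-np.log10(p), neglogp_cap)

    frac_m = het_m[idx] / (het_m[idx] + hom_m[idx])
    frac_f = het_f[idx] / (het_f[idx] + hom_f[idx])
    direction = np.where(
        frac_m > frac_f, Direction.MALE_HET.value,
        np.where(frac_f > frac_m, Direction.FEMALE_HET.value, Direction.NONE.value),
    )
    complete = n_missing[idx] == 0
    fully = complete & (
        ((het_m[idx] == n_m) & (hom_f[idx] == n_f))
        | ((hom_m[idx] == n_m) & (het_f[idx] == n_f))
    )
    return pd.DataFrame(
        {
            "contig": genotypes.contigs[idx],
            "pos": genotypes.positions[idx],
            "het_males": het_m[idx],
            "hom_males": hom_m[idx],
            "het_females": het_f[idx],
            "hom_females": hom_f[idx],
            "n_missing": n_missing[idx],
            "p": p,
            "neg_log10_p": neglogp,
            "fully_associated": fully,
            "direction": direction,
        }
    )


def flag_fully_associated(associations: pd.DataFrame) -> pd.DataFrame:
    """Subset of variants entirely associated with sex (cohort-complete)."""
    flagged = associations[associations["fully_associated"]]
    return flagged.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)


def density_windows(
    flagged: pd.DataFrame,
    contigs: ContigTable,
    window: int = DEFAULT_DENSITY_WINDOW,
    min_count: int = DEFAULT_DENSITY_MIN_COUNT,
) -> pd.DataFrame:
    """Non-overlapping ``window`` bp tiles (anchored at 0) holding strictly
    more than ``min_count`` flagged variants; direction is the common
    direction of the counted variants, else MIXED."""
    rows = []
    lengths = contigs.lengths
    for contig, sub in flagged.groupby("contig", sort=True):
        length = lengths.get(str(contig))
        tiles = sub["pos"] // window
        for tile, tile_sub in sub.groupby(tiles, sort=True):
            count = len(tile_sub)
            if count <= min_count:
                continue
            dirs = set(tile_sub["direction"])
            direction = dirs.pop() if len(dirs) == 1 else Direction.MIXED.value
            start = int(tile) * window
            end = start + window
            if length is not None:
                end = min(end, length)
            rows.append((contig, start, end, count, direction))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "count", "direction"]
    )
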