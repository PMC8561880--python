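"""Windowed read-depth contrasts between sexes and sex-specific zero-depth tracts.

The scan mirrors a classic coverage-based screen for sex chromosomes: mean
depth per sample in 1 kb bins, a two-sided Welch t-test of male vs female
window means per bin, and retention of windows with -log10(p) above a
threshold.  Sequence present in only one sex additionally shows up as
*zero-depth tracts*: maximal intervals where every individual of the other
sex has (near-)zero coverage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortDepths, ContigTable, Sex, SexedSample, validate_cohort

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1000
DEFAULT_NEGLOGP_THRESHOLD = 2.0
DEFAULT_P_FLOOR = 1e-300
DEFAULT_NEGLOGP_CAP = 300.0

WINDOW_COLUMNS = [
    "contig", "start", "end", "male_mean", "female_mean", "t", "p", "neg_log10_p",
]


@dataclass
class BinnedDepth:
    """Per-sample mean depth over a non-overlapping window tiling of one contig."""

    contig: str
    starts: np.ndarray  # 0-based inclusive
    ends: np.ndarray  # exclusive; final window may be shorter than bin_width
    samples: list[str]
    means: np.ndarray  # (n_windows, n_samples)


@dataclass(frozen=True)
class ZeroDepthTract:
    contig: str
    start: int
    end: int
    sex: Sex
    max_allowed_depth: int

    @property
    def length(self) -> int:
        return self.end - self.start


def bin_depths(
    depths: CohortDepths,
    contigs: ContigTable,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> list[BinnedDepth]:
    """Tile each contig with [0,b), [b,2b), ... windows of per-sample mean depth.

    A shorter terminal window is emitted and averaged over its true length.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    samples = sorted(depths)
    out: list[BinnedDepth] = []
    for contig, length in contigs.entries:
        starts = np.arange(0, length, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, length)
        widths = (ends - starts).astype(float)
        means = np.empty((len(starts), len(samples)), dtype=float)
        for j, sid in enumerate(samples):
            per_contig = depths[sid]
            if contig not in per_contig:
                raise ValueError(f"sample {sid!r} has no depth track for {contig!r}")
            arr = per_contig[contig]
            if len(arr) != length:
                raise ValueError(
                    f"track length {len(arr)} != contig length {length} for "
                    f"{sid}/{contig}"
                )
            means[:, j] = np.add.reduceat(arr.astype(float), starts) / widths
        out.append(BinnedDepth(contig, starts, ends, samples, means))
    return out


def welch_window_tests(
    binned: Sequence[BinnedDepth],
    cohort: Sequence[SexedSample],
    p_floor: float = DEFAULT_P_FLOOR,
    neglogp_cap: float = DEFAULT_NEGLOGP_CAP,
) -> pd.DataFrame:
    """Two-sided Welch t-test of male vs female window means, per window.

    Degenerate windows (both sexes zero variance) cannot use the t reference
    distribution: equal means give p = 1, t = 0; unequal means give the
    configured p floor and the -log10 cap, with t = +/-inf as a sentinel.
    A one-sided zero variance is handled by the ordinary Welch formula.
    """
    validate_cohort(cohort)
    sex_of = {s.sample_id: s.sex for s in cohort}
    frames = []
    for bd in binned:
        missing = [s for s in bd.samples if s not in sex_of]
        if missing:
            raise ValueError(f"samples without sex labels: {missing}")
        male_idx = [j for j, s in enumerate(bd.samples) if sex_of[s] is Sex.MALE]
        female_idx = [j for j, s in enumerate(bd.samples) if sex_of[s] is Sex.FEMALE]
        m = bd.means[:, male_idx]
        f = bd.means[:, female_idx]
        mm = m.mean(axis=1)
        fm = f.mean(axis=1)
        vm = m.var(axis=1, ddof=1)
        vf = f.var(axis=1, ddof=1)
        # degenerate (zero-variance) windows trip scipy's precision warning;
        # they are overwritten explicitly below
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(m, f, axis=1, equal_var=False)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        both_degenerate = (vm == 0) & (vf == 0)
        equal = both_degenerate & (mm == fm)
        forced = both_degenerate & (mm != fm)
        t[equal] = 0.0
        p[equal] = 1.0
        t[forced] = np.where(mm[forced] > fm[forced], np.inf, -np.inf)
        p[forced] = p_floor
        p = np.clip(p, p_floor, 1.0)
        neglogp = np.minimum(-np.log10(p), neglogp_cap)
        frames.append(
            pd.DataFrame(
                {
                    "contig": bd.contig,
                    "start": bd.starts,
                    "end": bd.ends,
                    "male_mean": mm,
                    "female_mean": fm,
                    "t": t,
                    "p": p,
                    "neg_log10_p": neglogp,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def filter_depth_windows(
    stats_df: pd.DataFrame, threshold: float = DEFAULT_NEGLOGP_THRESHOLD
) -> pd.DataFrame:
    """Retain windows with -log10(p) strictly greater than the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = stats_df[stats_df["neg_log10_p"] > threshold]
    return kept.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs where a boolean mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def zero_depth_tracts(
    depths: CohortDepths,
    cohort: Sequence[SexedSample],
    sex: Sex,
    contigs: ContigTable,
    max_allowed_depth: int = 0,
    min_tract_len: int = 1,
) -> list[ZeroDepthTract]:
    """Maximal intervals where *every* sample of ``sex`` stays at or below
    ``max_allowed_depth`` at every base, of length >= ``min_tract_len``.

    Requires densified tracks (explicit zeros), which the readers guarantee.
    """
    sample_ids = [s.sample_id for s in cohort if s.sex is sex]
    if not sample_ids:
        return []
    tracts: list[ZeroDepthTract] = []
    for contig, length in contigs.entries:
        stack = np.vstack([depths[sid][contig] for sid in sample_ids])
        mask = (stack <= max_allowed_depth).all(axis=0)
        for start, end in _mask_runs(mask):
            if end - start >= min_tract_len:
                tracts.append(
                    ZeroDepthTract(contig, int(start), int(end), sex, max_allowed_depth)
                )
    return tracts
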