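"""Marker-level DNA copy-number analysis.

The pipeline mirrors common practice for array-based tumor copy-number (CN)
data: impute missing markers from the nearest genomic neighbor, smooth
outlier markers and median-center each profile, segment each profile into
regions of constant copy number, test for recurrent gains/losses with a
cyclic-shift permutation scheme (which preserves each sample's serial
autocorrelation while destroying cross-sample locus alignment), localize
significant peaks with a bootstrap confidence interval, call gene-level
gains/losses against a fixed log2 threshold, and summarize per-sample genome
disruption with a chromosomal instability index.

Coordinates are 0-based half-open internally; on-disk formats (marker TSV,
SEG-style segment tables, BED-style annotation) use 1-based inclusive
positions, converted only at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DataError

__all__ = [
    "CopyNumberCohort",
    "Segment",
    "SegmentedProfile",
    "PeakCall",
    "GeneRegion",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_gene_regions",
    "read_arm_map",
    "write_segments",
    "impute_missing_markers",
    "smooth_and_center_profiles",
    "segment_profile",
    "cyclic_shift_peak_test",
    "peak_confidence_interval",
    "peel_and_repeat",
    "gene_level_copy_number",
    "cohort_gene_copy_number",
    "call_gene_event",
    "chromosomal_instability_index",
    "region_subtype_association",
]

MAD_TO_SD = 1.4826  # Gaussian consistency factor


@dataclass
class CopyNumberCohort:
    """Ordered marker-level log2 CN profiles for a set of samples.

    markers: DataFrame indexed by marker id with columns ``chrom`` and
        ``pos`` (bp), sorted by (chromosome, position), positions strictly
        increasing within each chromosome.
    values: marker x sample DataFrame of log2 ratios, rows aligned with
        ``markers``.
    arm_map: marker id -> chromosome-arm id, total over markers.
    """

    markers: pd.DataFrame
    values: pd.DataFrame
    arm_map: pd.Series

    def __post_init__(self) -> None:
        if not self.markers.index.equals(self.values.index):
            raise DataError("marker table and value matrix are not aligned")
        for chrom, block in self.markers.groupby("chrom", sort=False):
            pos = block["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise DataError(f"positions not strictly increasing on {chrom}")
        missing_arm = self.markers.index.difference(self.arm_map.index)
        if len(missing_arm):
            raise DataError(f"{len(missing_arm)} markers lack an arm assignment")

    @property
    def n_markers(self) -> int:
        return self.markers.shape[0]

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def chromosome_slices(self) -> dict:
        """Positional (start, stop) row ranges per chromosome, genome order."""
        out = {}
        chroms = self.markers["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = (start, i)
                start = i
        return out


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # bp, half-open internal coordinates
    end: int
    n_markers: int
    mean: float


@dataclass
class SegmentedProfile:
    """Piecewise-constant representation of one sample's CN profile."""

    sample_id: str
    segments: list = field(default_factory=list)
    # per-marker segment mean, aligned with the cohort marker index
    marker_values: pd.Series = None

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg.n_markers < 1:
                raise DataError("segment with no markers")


@dataclass(frozen=True)
class PeakCall:
    direction: str  # "gain" | "loss"
    peak_marker: str
    statistic: float
    p_value: float
    ci_left: str = None
    ci_right: str = None
    level: float = 0.95


@dataclass(frozen=True)
class GeneRegion:
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"gene {self.gene_id}: start must be < end")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _default_arm_map(markers: pd.DataFrame) -> pd.Series:
    """Assign every marker to the 'q' arm of its chromosome (no arm table)."""
    return pd.Series([f"{c}q" for c in markers["chrom"]], index=markers.index)


def read_marker_matrix(path, arm_boundaries=None) -> CopyNumberCohort:
    """Read a marker TSV (marker_id, chrom, pos, one column per sample).

    Positions on disk are 1-based; ``arm_boundaries`` optionally maps
    chromosome -> first position (1-based) of the q arm.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.set_index("marker_id")
    markers = df[["chrom", "pos"]].copy()
    markers["pos"] = markers["pos"].astype(int) - 1
    values = df.drop(columns=["chrom", "pos"]).astype(float)
    if arm_boundaries:
        arm = [
            f"{c}p" if p < arm_boundaries[c] - 1 else f"{c}q"
            for c, p in zip(markers["chrom"], markers["pos"])
        ]
        arm_map = pd.Series(arm, index=markers.index)
    else:
        arm_map = _default_arm_map(markers)
    return CopyNumberCohort(markers=markers, values=values, arm_map=arm_map)


def write_marker_matrix(cohort: CopyNumberCohort, path) -> None:
    out = cohort.markers.copy()
    out["pos"] = out["pos"] + 1
    out = pd.concat([out, cohort.values], axis=1)
    out.to_csv(path, sep="\t", index_label="marker_id")


def read_gene_regions(path) -> list:
    """Read BED-style TSV (chrom, start, end, gene_id), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    return [GeneRegion(r.name, r.chrom, int(r.start) - 1, int(r.end)) for r in df.itertuples()]


def read_arm_map(path, markers: pd.DataFrame) -> pd.Series:
    """Read BED-style arm TSV (chrom, start, end, arm_id) and map markers."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    arm = pd.Series(index=markers.index, dtype=object)
    for r in df.itertuples():
        mask = (markers["chrom"] == r.chrom) & (markers["pos"] >= int(r.start) - 1) & (
            markers["pos"] < int(r.end))
        arm[mask.to_numpy()] = r.name
    if arm.isna().any():
        raise DataError("arm table does not cover all markers")
    return arm


def write_segments(profiles, path) -> None:
    """Write SEG-style TSV (sample, chrom, start, end, n_markers, seg_mean)."""
    rows = []
    for prof in profiles:
        for seg in prof.segments:
            rows.append((prof.sample_id, seg.chrom, seg.start + 1, seg.end,
                         seg.n_markers, seg.mean))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                "n_markers", "seg_mean"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker hygiene
# ---------------------------------------------------------------------------

def impute_missing_markers(cohort: CopyNumberCohort) -> CopyNumberCohort:
    """Replace missing marker values with the genomically nearest non-missing
    value on the same chromosome (equidistant ties go to the upstream,
    lower-position marker)."""
    values = cohort.values.to_numpy(copy=True)
    for chrom, (lo, hi) in cohort.chromosome_slices().items():
        pos = cohort.markers["pos"].to_numpy()[lo:hi]
        block = values[lo:hi]
        for j in range(block.shape[1]):
            col = block[:, j]
            miss = np.isnan(col)
            if not miss.any():
                continue
            if miss.all():
                raise DataError(
                    f"sample {cohort.values.columns[j]!r} has no observed markers on {chrom}")
            obs_idx = np.flatnonzero(~miss)
            obs_pos = pos[obs_idx]
            for i in np.flatnonzero(miss):
                k = np.searchsorted(obs_pos, pos[i])
                if k == 0:
                    src = obs_idx[0]
                elif k == len(obs_pos):
                    src = obs_idx[-1]
                else:
                    dl = pos[i] - obs_pos[k - 1]
                    dr = obs_pos[k] - pos[i]
                    src = obs_idx[k - 1] if dl <= dr else obs_idx[k]
                col[i] = col[src]
    out = pd.DataFrame(values, index=cohort.values.index, columns=cohort.values.columns)
    return replace(cohort, values=out)


def smooth_and_center_profiles(cohort: CopyNumberCohort, window: int = 5,
                               z: float = 3.0) -> CopyNumberCohort:
    """Shrink outlier markers to the running median, then median-center.

    A marker is an outlier when its deviation from the within-chromosome
    running median (window of ``window`` markers) exceeds ``z`` times the
    sample's MAD-based residual scale.  After outlier removal each sample's
    genome-wide profile is centered to median 0.
    """
    values = cohort.values.to_numpy(copy=True)
    if np.isnan(values).any():
        raise DataError("smooth_and_center_profiles requires an imputed cohort")
    runmed = np.empty_like(values)
    for chrom, (lo, hi) in cohort.chromosome_slices().items():
        runmed[lo:hi] = ndimage.median_filter(
            values[lo:hi], size=(window, 1), mode="nearest")
    resid = values - runmed
    med_resid = np.median(resid, axis=0)
    scale = MAD_TO_SD * np.median(np.abs(resid - med_resid), axis=0)
    outlier = np.abs(resid) > z * scale
    values = np.where(outlier, runmed, values)
    values = values - np.median(values, axis=0)
    out = pd.DataFrame(values, index=cohort.values.index, columns=cohort.values.columns)
    return replace(cohort, values=out)


# ---------------------------------------------------------------------------
# Segmentation (recursive binary splitting)
# ---------------------------------------------------------------------------

def _best_split(x: np.ndarray, min_seg: int):
    """Best breakpoint by two-sample pooled t statistic; returns (k, p)."""
    n = len(x)
    if n < 2 * min_seg:
        return None, 1.0
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    ks = np.arange(min_seg, n - min_seg + 1)  # left part is x[:k]
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = csum[ks - 1]
    s2 = csum[-1] - s1
    q1 = csq[ks - 1]
    q2 = csq[-1] - q1
    ss1 = q1 - s1 * s1 / n1
    ss2 = q2 - s2 * s2 / n2
    pooled = (ss1 + ss2) / (n - 2)
    denom = np.sqrt(np.maximum(pooled, 0) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(s1 / n1 - s2 / n2) / denom
    t = np.where(denom == 0, 0.0, t)
    best = int(np.argmax(t))
    p = 2 * stats.t.sf(t[best], df=n - 2)
    return int(ks[best]), float(p)


def segment_profile(cohort: CopyNumberCohort, sample_id: str, min_seg: int = 3,
                    alpha: float = 0.01) -> SegmentedProfile:
    """Segment one sample's smoothed profile by recursive binary splitting.

    Splits are accepted while the two-sample t test at the best candidate
    breakpoint has p < ``alpha`` and both sides keep >= ``min_seg`` markers.
    """
    col = cohort.values[sample_id].to_numpy()
    positions = cohort.markers["pos"].to_numpy()
    seg_values = np.empty_like(col)
    segments = []
    for chrom, (lo, hi) in cohort.chromosome_slices().items():
        stack = [(lo, hi)]
        bounds = []
        while stack:
            a, b = stack.pop()
            k, p = _best_split(col[a:b], min_seg)
            if k is not None and p < alpha:
                stack.append((a, a + k))
                stack.append((a + k, b))
            else:
                bounds.append((a, b))
        for a, b in sorted(bounds):
            mean = float(col[a:b].mean())
            seg_values[a:b] = mean
            segments.append(Segment(chrom, int(positions[a]),
                                    int(positions[b - 1]) + 1, b - a, mean))
    marker_values = pd.Series(seg_values, index=cohort.values.index)
    return SegmentedProfile(sample_id=sample_id, segments=segments,
                            marker_values=marker_values)


# ---------------------------------------------------------------------------
# Recurrent aberrations: cyclic-shift permutation test
# ---------------------------------------------------------------------------

def _column_sums(values: np.ndarray) -> np.ndarray:
    return values.sum(axis=1)


def cyclic_shift_peak_test(cohort: CopyNumberCohort, direction: str,
                           n_perm: int = 250, seed=None) -> PeakCall:
    """Test for a recurrent gain (loss) by cyclic-shift permutation.

    The observed statistic is the max (gain) or min (loss) over markers of
    the cross-sample sum.  Each null replicate independently rotates every
    sample's genome-wide marker vector by a uniform random offset and
    recomputes the extreme; the p-value uses the add-one estimator with an
    inclusive comparison.  Ties at the extreme resolve to the first marker
    in genome order.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    if direction not in ("gain", "loss"):
        raise DataError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    values = cohort.values.to_numpy()
    m, n = values.shape
    sums = _column_sums(values)
    sign = 1.0 if direction == "gain" else -1.0
    obs = float(np.max(sign * sums))
    peak_idx = int(np.argmax(sign * sums))
    hits = 0
    for _ in range(n_perm):
        offsets = rng.integers(0, m, size=n)
        total = np.zeros(m)
        for j in range(n):
            total += np.roll(values[:, j], offsets[j])
        if np.max(sign * total) >= obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PeakCall(direction=direction,
                    peak_marker=str(cohort.values.index[peak_idx]),
                    statistic=float(sums[peak_idx]), p_value=p)


def peak_confidence_interval(cohort: CopyNumberCohort, direction: str,
                             level: float = 0.95, n_boot: int = 500,
                             seed=None) -> tuple:
    """Bootstrap confidence interval for the peak marker position.

    Samples are resampled with replacement; on each replicate the peak is
    relocated within the observed peak's chromosome, and the CI is the
    genome-ordered interval between the (1-level)/2 and 1-(1-level)/2
    quantiles of the bootstrap peak positions.
    """
    rng = np.random.default_rng(seed)
    values = cohort.values.to_numpy()
    m, n = values.shape
    sign = 1.0 if direction == "gain" else -1.0
    peak_idx = int(np.argmax(sign * _column_sums(values)))
    chrom = cohort.markers["chrom"].iloc[peak_idx]
    lo, hi = cohort.chromosome_slices()[chrom]
    block = values[lo:hi]
    boot_idx = np.empty(n_boot, dtype=int)
    for b in range(n_boot):
        cols = rng.integers(0, n, size=n)
        total = block[:, cols].sum(axis=1)
        boot_idx[b] = lo + int(np.argmax(sign * total))
    alpha = (1 - level) / 2
    left = int(np.percentile(boot_idx, 100 * alpha, method="lower"))
    right = int(np.percentile(boot_idx, 100 * (1 - alpha), method="higher"))
    left = min(left, peak_idx)
    right = max(right, peak_idx)
    return str(cohort.values.index[left]), str(cohort.values.index[right])


def _peel_peak(cohort: CopyNumberCohort, peak_idx: int, direction: str) -> CopyNumberCohort:
    """Remove a detected peak's signal so further peaks can be found.

    For every carrier sample (value at the peak marker beyond its chromosome
    median in the peak direction) the contiguous run of markers around the
    peak that stays beyond the chromosome median is reset to that median.
    """
    values = cohort.values.to_numpy(copy=True)
    chrom = cohort.markers["chrom"].iloc[peak_idx]
    lo, hi = cohort.chromosome_slices()[chrom]
    sign = 1.0 if direction == "gain" else -1.0
    k = peak_idx - lo
    for j in range(values.shape[1]):
        block = values[lo:hi, j]
        med = np.median(block)
        if sign * (block[k] - med) <= 0:
            continue  # not a carrier
        a = k
        while a > 0 and sign * (block[a - 1] - med) > 0:
            a -= 1
        b = k
        while b < len(block) - 1 and sign * (block[b + 1] - med) > 0:
            b += 1
        block[a:b + 1] = med
        values[lo:hi, j] = block
    out = pd.DataFrame(values, index=cohort.values.index, columns=cohort.values.columns)
    return replace(cohort, values=out)


def peel_and_repeat(cohort: CopyNumberCohort, direction: str, n_peaks: int = 5,
                    n_perm: int = 250, alpha: float = 0.05, seed=None,
                    n_boot: int = 500, level: float = 0.95,
                    with_ci: bool = True) -> list:
    """Iteratively detect up to ``n_peaks`` significant recurrent aberrations.

    After each significant peak its signal is peeled from the carrier
    samples and the cyclic-shift test repeats.  Detection stops at the first
    peak with p >= ``alpha``.  Each returned PeakCall carries the bootstrap
    CI computed on the cohort state in which it was detected.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(2 * n_peaks)
    peaks = []
    current = cohort
    for r in range(n_peaks):
        call = cyclic_shift_peak_test(current, direction, n_perm=n_perm,
                                      seed=seeds[2 * r])
        if call.p_value >= alpha:
            break
        if with_ci:
            left, right = peak_confidence_interval(
                current, direction, level=level, n_boot=n_boot, seed=seeds[2 * r + 1])
            call = replace(call, ci_left=left, ci_right=right, level=level)
        peaks.append(call)
        peak_idx = current.values.index.get_loc(call.peak_marker)
        current = _peel_peak(current, peak_idx, direction)
    return peaks


# ---------------------------------------------------------------------------
# Gene-level events
# ---------------------------------------------------------------------------

def gene_level_copy_number(profile: SegmentedProfile, markers: pd.DataFrame,
                           gene: GeneRegion, n_flank: int = 1,
                           max_distance: int = 1_000_000) -> float:
    """Mean segmented CN over markers inside the gene plus the nearest
    flanking marker on each side ("immediately adjacent")."""
    chrom_mask = (markers["chrom"] == gene.chrom).to_numpy()
    if not chrom_mask.any():
        raise DataError(f"gene {gene.gene_id}: chromosome {gene.chrom} not covered")
    pos = markers["pos"].to_numpy()[chrom_mask]
    seg_vals = profile.marker_values.to_numpy()[chrom_mask]
    inside = (pos >= gene.start) & (pos < gene.end)
    idx = list(np.flatnonzero(inside))
    if n_flank:
        before = np.flatnonzero(pos < gene.start)
        after = np.flatnonzero(pos >= gene.end)
        idx = list(before[-n_flank:]) + idx + list(after[:n_flank])
    if not idx:
        raise DataError(f"gene {gene.gene_id}: no markers on {gene.chrom}")
    dist = [max(gene.start - pos[i], pos[i] - gene.end + 1, 0) for i in idx]
    if min(dist) > max_distance:
        raise DataError(
            f"gene {gene.gene_id}: no marker within {max_distance} bp")
    return float(np.mean(seg_vals[idx]))


def cohort_gene_copy_number(profiles, markers: pd.DataFrame, gene: GeneRegion,
                            n_flank: int = 1) -> pd.Series:
    """Per-sample gene-level copy number over a collection of profiles."""
    return pd.Series({p.sample_id: gene_level_copy_number(p, markers, gene, n_flank)
                      for p in profiles})


def call_gene_event(value: float, threshold: float = 0.35) -> str:
    """Classify a gene-level CN value as gain / neutral / loss.

    The threshold is strict: values exactly at +-threshold are neutral.  The
    default 0.35 corresponds to roughly two standard deviations of segmented
    CN values in a typical tumor cohort.
    """
    if not np.isfinite(value):
        raise DataError("non-finite gene-level value")
    if value > threshold:
        return "gain"
    if value < -threshold:
        return "loss"
    return "neutral"


# ---------------------------------------------------------------------------
# Chromosomal instability and subtype association
# ---------------------------------------------------------------------------

def chromosomal_instability_index(values: pd.Series, arm_map: pd.Series) -> float:
    """Median over chromosome arms of the arm-wise median |CN value|.

    ``values`` are one sample's smoothed segmented values indexed by marker.
    Arms with no markers are excluded with a warning.
    """
    arm_medians = []
    for arm, idx in values.groupby(arm_map.reindex(values.index)).groups.items():
        vals = values.loc[idx]
        if len(vals) == 0:
            warnings.warn(f"arm {arm} has no markers; excluded")
            continue
        arm_medians.append(float(np.median(np.abs(vals))))
    if not arm_medians:
        raise DataError("no arms with markers")
    return float(np.median(arm_medians))


def region_subtype_association(cohort: CopyNumberCohort, labels: pd.Series,
                               region: tuple, n_tests: int = 1) -> dict:
    """Kruskal-Wallis association between mean CN over a region and subtype.

    ``region`` is a (left_marker_id, right_marker_id) genome-order interval,
    e.g. a peak confidence interval.  ``n_tests`` applies an optional
    Bonferroni adjustment over the number of regions examined.
    """
    left, right = region
    i = cohort.values.index.get_loc(left)
    j = cohort.values.index.get_loc(right)
    if j < i:
        raise DataError("region right marker precedes left marker")
    means = cohort.values.iloc[i:j + 1].mean(axis=0)
    labels = labels.reindex(means.index).dropna()
    groups = [means[labels.index][labels == g].to_numpy() for g in sorted(labels.unique())]
    if len(groups) < 2:
        raise DataError("need at least 2 subtypes")
    if all(np.allclose(g, groups[0][0]) for g in groups):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*groups)
    return {"statistic": float(stat), "p_value": float(p),
            "p_adjusted": min(1.0, float(p) * n_tests), "n": int(labels.size)}
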