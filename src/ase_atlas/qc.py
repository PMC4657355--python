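"""Pre-test quality control for heterozygous SNPs.

Apparent heterozygous calls inside long stretches of true homozygosity are
genotyping artefacts and masquerade as mono-allelic expression, so they are
hunted with a windowed runs-of-homozygosity (RoH) scan and removed together
with variants failing private-detection and population-heterozygosity
checks. Per-site depth/major-allele-agreement gating and the validation
cohort's mapping-bias metric live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoHRegion",
    "detect_roh",
    "apply_sequence_error_filters",
    "depth_agreement_filter",
    "compute_bias",
    "bias_filter",
]


@dataclass(frozen=True)
class RoHRegion:
    """A merged run-of-homozygosity region, half-open [start, end)."""

    chrom: str
    start: int
    end: int
    n_windows: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty RoH region {self.chrom}:{self.start}-{self.end}")

    def contains(self, pos: int) -> bool:
        """1-based position inside the half-open 0-based interval."""
        return self.start < pos <= self.end


def detect_roh(
    het_positions: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
    step: int = 50_000,
    min_het: int = 6,
    require_both_neighbours: bool = False,
) -> list[RoHRegion]:
    """Windowed runs-of-homozygosity scan.

    Steps through each chromosome in ``step``-sized offsets examining
    ``window``-sized windows anchored at coordinate 0; a window with fewer
    than ``min_het`` heterozygous SNPs is flagged. A flagged window is
    deemed homozygous when an immediately adjacent window is also flagged
    (both neighbours, if ``require_both_neighbours``); deemed windows are
    merged by union into regions.

    ``het_positions`` maps chromosome -> sorted 1-based SNP positions.
    Returns 0-based half-open regions clipped to chromosome length.
    """
    if window < step:
        raise ValueError("window must be >= step")
    regions: list[RoHRegion] = []
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(sorted(het_positions.get(chrom, ())), dtype=np.int64)
        n_windows = max(1, math.ceil(max(length - window, 0) / step) + 1)
        starts = np.arange(n_windows, dtype=np.int64) * step
        ends = np.minimum(starts + window, length)
        # het count per window: positions are 1-based, window [s, s+window)
        lo = np.searchsorted(pos, starts + 1, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        flagged = (hi - lo) < min_het

        deemed = np.zeros_like(flagged)
        for i in range(n_windows):
            if not flagged[i]:
                continue
            left = flagged[i - 1] if i > 0 else False
            right = flagged[i + 1] if i + 1 < n_windows else False
            if require_both_neighbours:
                ok = (left or i == 0) and (right or i + 1 == n_windows)
                ok = ok and (left or right)  # need at least one real neighbour
            else:
                ok = left or right
            deemed[i] = ok

        # merge deemed windows by union
        i = 0
        while i < n_windows:
            if not deemed[i]:
                i += 1
                continue
            j = i
            end = ends[i]
            while j + 1 < n_windows and deemed[j + 1] and starts[j + 1] <= end:
                j += 1
                end = max(end, ends[j])
            regions.append(RoHRegion(chrom, int(starts[i]), int(end), n_windows=j - i + 1))
            i = j + 1
    return regions


def positions_in_roh(
    chroms: Sequence[str], positions: Sequence[int], regions: Iterable[RoHRegion]
) -> np.ndarray:
    """Boolean mask: which (chrom, 1-based pos) pairs fall in a region."""
    by_chrom: dict[str, list[RoHRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    mask = np.zeros(len(positions), dtype=bool)
    for i, (c, p) in enumerate(zip(chroms, positions)):
        mask[i] = any(r.contains(int(p)) for r in by_chrom.get(c, ()))
    return mask


def apply_sequence_error_filters(
    variants: pd.DataFrame,
    private_set: set | None = None,
    population_het_set: set | None = None,
    roh_regions: Iterable[RoHRegion] = (),
) -> pd.DataFrame:
    """Flag likely genotyping/sequencing-error SNPs.

    A SNP is removed when it (1) was not rediscovered in the animal's own
    private variant detection, (2) is not heterozygous in any other animal
    of the reference population, or (3) lies inside a run of homozygosity.
    The rules are pure predicates, so the kept set is order-independent;
    each removed SNP carries the first failing rule as its primary reason.

    ``private_set``/``population_het_set`` are snp_id sets; when None the
    corresponding boolean columns ``private_detected``/``pop_het`` of
    ``variants`` are used.

    Returns the input with added columns ``in_roh``, ``qc_keep``,
    ``qc_reason``.
    """
    out = variants.copy()
    if private_set is not None:
        private_ok = out["snp_id"].isin(private_set).to_numpy()
    else:
        private_ok = out.get("private_detected", pd.Series(True, index=out.index)).to_numpy(dtype=bool)
    if population_het_set is not None:
        pop_ok = out["snp_id"].isin(population_het_set).to_numpy()
    else:
        pop_ok = out.get("pop_het", pd.Series(True, index=out.index)).to_numpy(dtype=bool)
    in_roh = positions_in_roh(out["chrom"].tolist(), out["pos"].tolist(), roh_regions)

    reason = np.full(len(out), "", dtype=object)
    reason[~in_roh & ~pop_ok] = "pop_het"
    reason[~private_ok] = "not_private"
    # precedence: not_private, pop_het, roh — but roh wins for sites in RoH
    reason[in_roh] = "roh"
    keep = private_ok & pop_ok & ~in_roh
    reason[keep] = ""

    out["in_roh"] = in_roh
    out["qc_keep"] = keep
    out["qc_reason"] = reason
    return out


def depth_agreement_filter(
    counts: pd.DataFrame, min_depth: int = 10
) -> pd.DataFrame:
    """Depth and cross-alignment majority-allele agreement gate.

    Keeps a SNP x tissue record iff both alignment totals reach
    ``min_depth`` (inclusive) and the most abundant *allele* is the same in
    the maternal and paternal alignments. In allele space the maternal
    alignment sees the maternal allele r_m times and the other allele a_m
    times; the paternal alignment sees the paternal allele r_p times and
    the other allele a_p times. Ties in either alignment count as
    agreement. Adds ``filter_keep`` and ``filter_reason`` columns.
    """
    out = counts.copy()
    r_m = out["r_m"].to_numpy(dtype=float)
    a_m = out["a_m"].to_numpy(dtype=float)
    r_p = out["r_p"].to_numpy(dtype=float)
    a_p = out["a_p"].to_numpy(dtype=float)
    m_tot = r_m + a_m
    p_tot = r_p + a_p
    depth_ok = (m_tot >= min_depth) & (p_tot >= min_depth)

    # majority allele per alignment: +1 = maternal allele, -1 = paternal, 0 = tie
    maj_m = np.sign(r_m - a_m)
    maj_p = np.sign(a_p - r_p)
    agree = (maj_m == 0) | (maj_p == 0) | (maj_m == maj_p)

    reason = np.full(len(out), "", dtype=object)
    reason[~agree] = "discordant_major"
    reason[~depth_ok] = "depth"
    out["filter_keep"] = depth_ok & agree
    out["filter_reason"] = np.where(depth_ok & agree, "", reason)
    return out


def compute_bias(n_apa, n_bpb, n_apb, n_bpa):
    """Reference-allele mapping-bias metric for the validation cohort.

    bias = sqrt((n_APA * n_BPB) / (n_APB * n_BPA)) where n_XPY counts reads
    carrying allele X aligned to the parental genome carrying allele Y.
    Matching counts in the numerator, cross-mapping counts in the
    denominator: a value far from 1 means reads align preferentially to the
    genome carrying their own allele. NaN (undefined) when the denominator
    is zero. Accepts scalars or arrays.
    """
    arrs = [np.asarray(x, dtype=float) for x in (n_apa, n_bpb, n_apb, n_bpa)]
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("bias counts must be non-negative")
    n_apa, n_bpb, n_apb, n_bpa = arrs
    denom = n_apb * n_bpa
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, np.sqrt(n_apa * n_bpb / np.where(denom > 0, denom, 1.0)), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def bias_filter(bias, threshold: float = 2.0, symmetric: bool = True):
    """Keep SNPs whose mapping bias is defined and below ``threshold``.

    By default the rule is symmetric, max(bias, 1/bias) < threshold, since
    the direction of the ratio is arbitrary with respect to allele
    labelling; ``symmetric=False`` applies the literal one-sided
    bias < threshold rule. Undefined (NaN) bias always fails.
    """
    bias = np.asarray(bias, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        effective = np.maximum(bias, 1.0 / bias) if symmetric else bias
    out = ~np.isnan(bias) & (effective < threshold)
    if out.ndim == 0:
        return bool(out)
    return out
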