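"""Calling bisulfite accessible regions (BARs) and measuring patch sizes.

Four size definitions are supported.  "Previous": per-molecule runs of >= 2
consecutively converted C sites, measured last-C to last-C (inclusive bp).
"New": the model-based expectation over the posterior segment-weight
distribution {w_{i,j,t}} at the cluster's peak conversion site.  Each has a
midpoint ("MP") variant that places boundaries halfway between the terminal
converted C and its nearest unconverted flanking C — the expected boundary
location when boundaries arrive as a Poisson process along the base-pair
axis.  A segment end at the amplicon edge contributes its last-C edge
(tau +/- 0.5), so a full-span segment reproduces the inclusive length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import SegmentationResult
from .io import MutationMatrix, SiteCounts


@dataclass
class BARCall:
    """A called accessible region in one cluster."""

    cluster: str
    strand: str
    peak_site: int
    site_span: tuple[int, int]          # [tau_i, tau_j] of the MAP segment
    run_span: tuple[int, int]           # [tau_first, tau_last] of the elevated run
    size_new: float                     # E[size], last-C boundaries
    size_new_mp: float                  # E[size], midpoint boundaries
    size_distribution: dict[tuple[int, int], float]
    run_positions: np.ndarray           # amplicon coords of the run's sites
    theta_mean: np.ndarray              # over the run's sites


@dataclass
class SequencePatch:
    """A per-molecule run of consecutively converted C sites."""

    seq_id: str
    first_converted: int
    last_converted: int
    run_length: int
    size_prev: float
    size_prev_mp: float


def _edges(positions: np.ndarray, i: int, j: int, mode: str) -> tuple[float, float]:
    """Left/right boundary of sites i..j (1-based indices into positions)."""
    tau = positions
    if mode == "last_c":
        return float(tau[i - 1]) - 0.5, float(tau[j - 1]) + 0.5
    if mode != "midpoint":
        raise ValueError(f"unknown mode {mode!r}")
    left = (tau[i - 2] + tau[i - 1]) / 2.0 if i > 1 else float(tau[i - 1]) - 0.5
    right = (tau[j - 1] + tau[j]) / 2.0 if j < tau.size else float(tau[j - 1]) + 0.5
    return float(left), float(right)


def segment_size(positions: np.ndarray, i: int, j: int, mode: str) -> float:
    """Size in bp of the segment spanning sites i..j under a boundary mode.

    last_c: inclusive length tau_j - tau_i + 1.  midpoint: distance between
    the flanking-C midpoints, falling back to the last-C edge at amplicon
    ends.
    """
    left, right = _edges(positions, i, j, mode)
    return right - left


def model_patch_size(
    i_idx: np.ndarray,
    j_idx: np.ndarray,
    w: np.ndarray,
    positions: np.ndarray,
    mode: str = "last_c",
) -> tuple[float, dict[tuple[int, int], float]]:
    """Expected BAR size under the posterior segment distribution at a site.

    Returns (expectation, {(i, j) -> weight}) with weights summing to 1.
    """
    if not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("segment weights must sum to 1")
    sizes = np.array([segment_size(positions, i, j, mode) for i, j in zip(i_idx, j_idx)])
    dist = {(int(i), int(j)): float(wt) for i, j, wt in zip(i_idx, j_idx, w) if wt > 1e-12}
    return float(w @ sizes), dist


def call_bars(
    result: SegmentationResult,
    counts: SiteCounts,
    cluster: str = "cluster",
    strand: str = "top",
    threshold_factor: float = 3.0,
    min_run: int = 2,
) -> list[BARCall]:
    """Call BARs from a cluster's segmentation posterior.

    A cluster contains a nontrivial BAR iff >= ``min_run`` consecutive C
    sites have posterior accessibility >= ``threshold_factor`` x mu0; each
    maximal such run yields one call, anchored at its peak observed-frequency
    site and spanned by the maximum-a-posteriori segment at that site.
    An empty return means "no typical patch".
    """
    theta = result.theta_mean
    thr = threshold_factor * result.hyper.mu0
    above = theta >= thr
    calls: list[BARCall] = []
    N = theta.size
    t = 0
    while t < N:
        if not above[t]:
            t += 1
            continue
        start = t
        while t < N and above[t]:
            t += 1
        end = t - 1  # inclusive 0-based
        if end - start + 1 < min_run:
            continue
        freqs = counts.freq[start : end + 1]
        peak0 = start + int(np.argmax(freqs))
        i_idx, j_idx, w = result.segment_weights(peak0 + 1)
        map_k = int(np.argmax(w))
        i_map, j_map = int(i_idx[map_k]), int(j_idx[map_k])
        size_new, dist = model_patch_size(i_idx, j_idx, w, result.positions, "last_c")
        size_new_mp, _ = model_patch_size(i_idx, j_idx, w, result.positions, "midpoint")
        calls.append(
            BARCall(
                cluster=cluster,
                strand=strand,
                peak_site=int(result.positions[peak0]),
                site_span=(int(result.positions[i_map - 1]), int(result.positions[j_map - 1])),
                run_span=(int(result.positions[start]), int(result.positions[end])),
                size_new=size_new,
                size_new_mp=size_new_mp,
                size_distribution=dist,
                run_positions=result.positions[start : end + 1].copy(),
                theta_mean=theta[start : end + 1].copy(),
            )
        )
    return calls


def previous_patch_caller(
    matrix: MutationMatrix, min_run: int = 2
) -> list[SequencePatch]:
    """Per-molecule patches: maximal runs of >= min_run consecutive converted Cs.

    Independent of any clustering; sizes under both the last-C and midpoint
    conventions.
    """
    patches: list[SequencePatch] = []
    pos = matrix.positions
    for sid, row in zip(matrix.seq_ids, matrix.calls):
        t = 0
        N = row.size
        while t < N:
            if not row[t]:
                t += 1
                continue
            start = t
            while t < N and row[t]:
                t += 1
            end = t - 1
            if end - start + 1 < min_run:
                continue
            patches.append(
                SequencePatch(
                    seq_id=sid,
                    first_converted=int(pos[start]),
                    last_converted=int(pos[end]),
                    run_length=end - start + 1,
                    size_prev=segment_size(pos, start + 1, end + 1, "last_c"),
                    size_prev_mp=segment_size(pos, start + 1, end + 1, "midpoint"),
                )
            )
    return patches


def patch_summary_table(
    bar_calls: list[BARCall],
    sequence_patches_by_cluster: dict[str, list[SequencePatch]],
    weighted: bool = False,
) -> pd.DataFrame:
    """Grand means of the four patch-size definitions with SEM over clusters.

    Rows: Previous, New, Previous-MP, New-MP.  Cluster-level values are the
    mean per-molecule patch size ("Previous") or the model expectation at the
    peak site ("New"); grand means average cluster values unweighted by
    default (``weighted=True`` weights by patch/sequence counts).
    """
    if not bar_calls:
        raise ValueError("no BAR calls to summarize")
    prev, prev_mp, prev_n = [], [], []
    for name, patches in sequence_patches_by_cluster.items():
        if not patches:
            continue
        prev.append(float(np.mean([p.size_prev for p in patches])))
        prev_mp.append(float(np.mean([p.size_prev_mp for p in patches])))
        prev_n.append(len(patches))
    new = [b.size_new for b in bar_calls]
    new_mp = [b.size_new_mp for b in bar_calls]

    def summarize(values, wts):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return np.nan, np.nan, 0
        if weighted and wts is not None:
            wts = np.asarray(wts, dtype=float)
            mean = float(values @ wts / wts.sum())
        else:
            mean = float(values.mean())
        sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
        return mean, sem, values.size

    rows = {
        "Previous": summarize(prev, prev_n),
        "New": summarize(new, None),
        "Previous-MP": summarize(prev_mp, prev_n),
        "New-MP": summarize(new_mp, None),
    }
    df = pd.DataFrame(rows, index=["mean_bp", "sem", "n_clusters"]).T
    df["n_clusters"] = df["n_clusters"].astype(int)
    df["sem_defined"] = df["n_clusters"] > 1
    return df


def bars_to_bed(bar_calls: list[BARCall], chrom: str = "amplicon") -> str:
    """BED6 text for called BARs (0-based half-open; internal coords are
    1-based inclusive).  Score column holds peak posterior accessibility."""
    lines = [
        "# BED 0-based half-open; converted from 1-based inclusive amplicon coordinates",
        "# patch sizes: last-C = inclusive bp length tau_last - tau_first + 1",
    ]
    for b in bar_calls:
        start, end = b.site_span
        lines.append(
            f"{chrom}\t{start - 1}\t{end}\t{b.cluster}\t"
            f"{float(b.theta_mean.max()):.6g}\t{'+' if b.strand == 'top' else '-'}"
        )
    return "\n".join(lines) + "\n"
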