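"""Spatial relationships between BARs, SHM hotspots and external score tracks.

Covers: selection of the top-k most mutated sites per strand, site-to-site
Pearson correlation, Gaussian kernel smoothing for cross-strand comparison
(C and G sites never coincide, so both tracks are evaluated on the full
amplicon grid), posterior-weighted signed distances from hotspots to BARs
with the 15 bp window analysis, moving-window score aggregation (e.g. for
G-quadruplex contribution tracks), and the strand accessibility chi-squared
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bars import BARCall
from .io import SiteCounts


@dataclass
class SiteTrack:
    """A per-position real-valued signal on the 1..L amplicon grid."""

    positions: np.ndarray
    values: np.ndarray
    strand: str = "top"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")


def track_from_counts(counts: SiteCounts, L: int, strand: str = "top") -> SiteTrack:
    """Embed per-site frequencies on the full 1..L grid, zero elsewhere."""
    values = np.zeros(L)
    values[counts.positions.astype(int) - 1] = counts.freq
    return SiteTrack(positions=np.arange(1, L + 1), values=values, strand=strand)


def top_k_sites(shm_counts: dict[str, SiteCounts], k: int = 25) -> pd.DataFrame:
    """The k most mutated sites per strand, concatenated across strands.

    Sorted by descending mutation frequency; ties broken by ascending
    position.  Columns: strand, position, freq.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frames = []
    for strand, counts in shm_counts.items():
        if k > counts.n_sites:
            raise ValueError(f"k={k} exceeds {counts.n_sites} sites on {strand}")
        df = pd.DataFrame({
            "strand": strand,
            "position": counts.positions.astype(int),
            "freq": counts.freq,
        })
        df = df.sort_values(["freq", "position"], ascending=[False, True], kind="stable")
        frames.append(df.head(k))
    return pd.concat(frames, ignore_index=True)


def site_correlation(a, b, method: str = "pearson") -> tuple[float, float]:
    """Correlation of paired per-site values with a two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in input vector")
    if method == "pearson":
        r = stats.pearsonr(a, b)
    elif method == "spearman":
        r = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def gaussian_smooth(track: SiteTrack, sigma: float = 1.0) -> SiteTrack:
    """Discrete Gaussian smoothing over bp positions, truncated at 4 sigma.

    The kernel is renormalized where it overhangs the track ends, so a
    constant track is left unchanged and mass is conserved away from edges.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = max(1, int(np.ceil(4.0 * sigma)))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(track.values, kernel, mode="same")
    den = np.convolve(np.ones_like(track.values), kernel, mode="same")
    return SiteTrack(positions=track.positions, values=num / den, strand=track.strand)


def weighted_distance_to_bar(site: float, bar: BARCall, method: str = "centroid") -> float:
    """Signed bp distance from a site to a BAR.

    ``centroid`` (default): each BAR site's distance is weighted by its
    posterior accessibility ("posterior response probability to bisulfite");
    positive means the site lies 3' of the BAR's weighted centroid.
    ``edge``: signed distance to the nearest BAR site, 0 inside the span.
    """
    theta = np.asarray(bar.theta_mean, dtype=float)
    tau = np.asarray(bar.run_positions, dtype=float)
    if method == "edge":
        if tau[0] <= site <= tau[-1]:
            return 0.0
        return float(site - tau[-1]) if site > tau[-1] else float(site - tau[0])
    if method != "centroid":
        raise ValueError(f"unknown method {method!r}")
    if theta.sum() <= 0:
        raise ValueError("BAR has no posterior mass")
    return float(((site - tau) * theta).sum() / theta.sum())


def nearest_bar_analysis(
    sites: pd.DataFrame,
    bars: list[BARCall],
    window: float = 15.0,
    method: str = "centroid",
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Distance from each hotspot to its nearest and second-nearest BAR.

    ``sites`` needs columns position and freq (e.g. from :func:`top_k_sites`).
    Returns the per-site table and two correlations: SHM frequency vs
    |distance| to the nearest BAR restricted to |distance| <= window, and vs
    the second-nearest distance.  BARs from both strands are pooled.
    """
    if not bars:
        raise ValueError("need at least one BAR")
    rows = []
    for _, s in sites.iterrows():
        d = np.array([weighted_distance_to_bar(s["position"], b, method) for b in bars])
        order = np.argsort(np.abs(d), kind="stable")
        nearest = order[0]
        second = order[1] if len(bars) > 1 else None
        rows.append({
            "position": int(s["position"]),
            "strand": s.get("strand", "na"),
            "shm_freq": float(s["freq"]),
            "nearest_bar": bars[nearest].cluster,
            "signed_distance_bp": float(d[nearest]),
            "second_nearest_bar": bars[second].cluster if second is not None else None,
            "second_distance_bp": float(d[second]) if second is not None else np.nan,
            "within_window": bool(abs(d[nearest]) <= window),
        })
    table = pd.DataFrame(rows)

    correlations: dict[str, tuple[float, float]] = {}
    near = table[table["within_window"]]
    if len(near) >= 3 and near["shm_freq"].nunique() > 1:
        correlations["nearest_within_window"] = site_correlation(
            near["shm_freq"], near["signed_distance_bp"].abs()
        )
    sec = table.dropna(subset=["second_distance_bp"])
    if len(sec) >= 3 and sec["shm_freq"].nunique() > 1:
        correlations["second_nearest"] = site_correlation(
            sec["shm_freq"], sec["second_distance_bp"].abs()
        )
    return table, correlations


def aggregate_window_scores(
    window_scores: list[tuple[int, np.ndarray]], L: int
) -> tuple[SiteTrack, np.ndarray]:
    """Average overlapping per-window score arrays onto the amplicon grid.

    Each (offset, scores) places scores at 1-based positions offset ..
    offset + len - 1.  Per position: mean over covering windows; uncovered
    positions get 0.  Returns (track, coverage counts).
    """
    total = np.zeros(L)
    coverage = np.zeros(L, dtype=int)
    for offset, scores in window_scores:
        scores = np.asarray(scores, dtype=float)
        if offset < 1 or offset + scores.size - 1 > L:
            raise ValueError(f"window at offset {offset} exceeds amplicon length {L}")
        total[offset - 1 : offset - 1 + scores.size] += scores
        coverage[offset - 1 : offset - 1 + scores.size] += 1
    values = np.divide(total, coverage, out=np.zeros(L), where=coverage > 0)
    return SiteTrack(positions=np.arange(1, L + 1), values=values), coverage


def strand_fraction_test(
    n_bar_top: int, n_total_top: int, n_bar_bottom: int, n_total_bottom: int
) -> tuple[float, float]:
    """2x2 chi-squared test (no continuity correction) comparing the
    fraction of BAR-bearing molecules between strands."""
    if n_total_top <= 0 or n_total_bottom <= 0:
        raise ValueError("totals must be positive")
    table = np.array([
        [n_bar_top, n_total_top - n_bar_top],
        [n_bar_bottom, n_total_bottom - n_bar_bottom],
    ])
    if np.any(table < 0):
        raise ValueError("BAR counts exceed totals")
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
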