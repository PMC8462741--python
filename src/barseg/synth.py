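"""Synthetic single-molecule conversion matrices with known ground truth.

Generates data under exactly the statistical model the segmentation assumes:
per-site conversion probabilities that are piecewise constant over the
informative sites, independent Bernoulli draws per molecule, and mixtures of
cluster archetypes over a shared site grid.  Also generates sparse SHM-like
hotspot matrices.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MutationMatrix

# Default geometry mirrors an IGHV amplicon: 346 bp with ~80 irregularly
# spaced C sites per strand; ~75% of molecules carry no patch, the rest
# split among five single-BAR archetypes.
DEFAULT_L = 346
DEFAULT_N_SITES = 80
DEFAULT_BASELINE_THETA = 0.01


@dataclass
class Segment:
    """An elevated accessibility segment over site indices (1-based, inclusive)."""

    start_site: int
    end_site: int
    theta: float

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.start_site < 1 or self.end_site < self.start_site:
            raise ValueError("invalid segment bounds")


@dataclass
class Component:
    """One mixture archetype: a proportion and its segments."""

    proportion: float
    segments: list[Segment] = field(default_factory=list)
    name: str = ""


@dataclass
class SyntheticSpec:
    """Ground-truth description of a simulated conversion matrix."""

    L: int = DEFAULT_L
    c_positions: np.ndarray | None = None
    n_sites: int = DEFAULT_N_SITES
    baseline_theta: float = DEFAULT_BASELINE_THETA
    components: list[Component] = field(default_factory=list)
    n_sequences: int = 1000
    strand: str = "top"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            self.components = [Component(proportion=1.0, name="background")]
        total = sum(c.proportion for c in self.components)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"component proportions must sum to 1, got {total}")
        if self.c_positions is None:
            self.c_positions = irregular_sites(self.L, self.n_sites, self.seed)
        self.c_positions = np.asarray(self.c_positions, dtype=int)
        self.n_sites = self.c_positions.size
        if np.any(np.diff(self.c_positions) <= 0):
            raise ValueError("c_positions must be strictly increasing")
        if self.c_positions[0] < 1 or self.c_positions[-1] > self.L:
            raise ValueError("c_positions must lie within [1, L]")
        for comp in self.components:
            for seg in comp.segments:
                if seg.end_site > self.n_sites:
                    raise ValueError("segment exceeds number of sites")

    def component_theta(self, idx: int) -> np.ndarray:
        """Per-site conversion probabilities of one archetype."""
        theta = np.full(self.n_sites, self.baseline_theta)
        for seg in self.components[idx].segments:
            theta[seg.start_site - 1 : seg.end_site] = seg.theta
        return theta


def irregular_sites(L: int, n_sites: int, seed: int = 0) -> np.ndarray:
    """Irregularly spaced site coordinates mimicking C density along DNA."""
    rng = np.random.default_rng(seed)
    if n_sites > L:
        raise ValueError("more sites than base pairs")
    pos = np.sort(rng.choice(np.arange(1, L + 1), size=n_sites, replace=False))
    return pos.astype(int)


def default_spec(n_sequences: int = 4000, seed: int = 0) -> SyntheticSpec:
    """The default fixture: a patternless majority plus five BAR archetypes.

    Mimics the observed cluster structure of a bisulfite-treated IGHV
    amplicon: ~75% of molecules with no patch and five clusters each
    carrying a single accessible region in a distinct subregion.
    """
    comps = [
        Component(proportion=0.754, segments=[], name="none"),
        Component(0.081, [Segment(12, 17, 0.45)], "bar_fw2"),
        Component(0.059, [Segment(30, 36, 0.40)], "bar_cdr2"),
        Component(0.045, [Segment(45, 49, 0.50)], "bar_fw3"),
        Component(0.035, [Segment(58, 64, 0.35)], "bar_cdr3"),
        Component(0.026, [Segment(70, 74, 0.55)], "bar_3prime"),
    ]
    return SyntheticSpec(components=comps, n_sequences=n_sequences, seed=seed)


def simulate_matrix(spec: SyntheticSpec) -> tuple[MutationMatrix, dict]:
    """Draw a conversion matrix from a spec.

    Each molecule draws its archetype from the mixture, then independent
    Bernoulli(theta_t) calls at every site.  Returns (matrix, truth) where
    truth holds per-sequence component labels, per-component theta vectors,
    and the segment spans in site indices.
    """
    rng = np.random.default_rng(spec.seed)
    props = np.array([c.proportion for c in spec.components])
    labels = rng.choice(len(spec.components), size=spec.n_sequences, p=props)
    thetas = np.vstack([spec.component_theta(i) for i in range(len(spec.components))])
    calls = (rng.random((spec.n_sequences, spec.n_sites)) < thetas[labels]).astype(np.uint8)
    matrix = MutationMatrix(
        strand=spec.strand,
        positions=spec.c_positions,
        calls=calls,
        seq_ids=[f"seq{i:06d}" for i in range(spec.n_sequences)],
    )
    truth = {
        "labels": labels,
        "component_names": [c.name for c in spec.components],
        "theta": thetas,
        "segments": {
            c.name: [(s.start_site, s.end_site, s.theta) for s in c.segments]
            for c in spec.components
        },
    }
    return matrix, truth


def simulate_shm(
    positions: np.ndarray,
    rates: np.ndarray,
    n_sequences: int,
    strand: str = "top",
    seed: int = 0,
) -> MutationMatrix:
    """Sparse SHM-like matrix: independent per-site Bernoulli at hotspot rates.

    Rates are capped at 0.05 — SHM is orders of magnitude sparser than
    bisulfite conversion.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0) or np.any(rates > 0.05):
        raise ValueError("SHM rates must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    calls = (rng.random((n_sequences, rates.size)) < rates).astype(np.uint8)
    return MutationMatrix(
        strand=strand,
        positions=np.asarray(positions, dtype=int),
        calls=calls,
        seq_ids=[f"shm{i:06d}" for i in range(n_sequences)],
    )


def spec_from_dict(d: dict) -> SyntheticSpec:
    """Build a spec from a plain mapping (YAML-friendly).

    Components are mappings with ``proportion``, optional ``name`` and
    ``segments`` given as [start_site, end_site, theta] triples.
    """
    comps = [
        Component(
            proportion=float(c["proportion"]),
            segments=[Segment(int(s[0]), int(s[1]), float(s[2])) for s in c.get("segments", [])],
            name=str(c.get("name", f"comp{i}")),
        )
        for i, c in enumerate(d.get("components", []))
    ]
    return SyntheticSpec(
        L=int(d.get("L", DEFAULT_L)),
        c_positions=np.asarray(d["c_positions"], dtype=int) if "c_positions" in d else None,
        n_sites=int(d.get("n_sites", DEFAULT_N_SITES)),
        baseline_theta=float(d.get("baseline_theta", DEFAULT_BASELINE_THETA)),
        components=comps,
        n_sequences=int(d.get("n_sequences", 1000)),
        strand=str(d.get("strand", "top")),
        seed=int(d.get("seed", 0)),
    )


def single_segment_spec(
    theta_in: float = 0.3,
    theta_out: float = 0.01,
    n_sequences: int = 500,
    n_sites: int = 60,
    start_site: int = 25,
    end_site: int = 36,
    L: int = 300,
    seed: int = 0,
) -> SyntheticSpec:
    """One elevated segment on a baseline — the boundary-recovery benchmark."""
    return SyntheticSpec(
        L=L,
        n_sites=n_sites,
        baseline_theta=theta_out,
        components=[Component(1.0, [Segment(start_site, end_site, theta_in)], "bar")],
        n_sequences=n_sequences,
        seed=seed,
    )
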