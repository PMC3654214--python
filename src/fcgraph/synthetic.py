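"""Synthetic multi-subject resting-state datasets with planted network structure.

The generator emulates the study design the pipeline targets: two resting
scans (pre and post a motor task) per subject, ~10 minutes at TR = 2.8 s,
116 parcellated regions whose slow fluctuations live in a 0.01-0.1 Hz band,
and a modular correlation structure.  A "learning" effect is planted as a
uniform correlation increment ``post_delta`` on within-module pairs of the
post session, so downstream comparisons have a known ground truth.

Each regional series is a band-limited Gaussian process: white noise is
band-passed with an ideal zero-phase filter, standardised, then mixed
across regions with the matrix square root of the planted correlation
matrix — giving exact control of the target covariance in expectation.

Toy graph fixtures and classic random-graph models used by the test suite
and the null-model stage live here too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from .connectivity import RegionalTimeSeries
from .graph import BinaryGraph

SESSIONS = ("pre", "post")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a planted-structure resting-state dataset.

    ``module_sizes`` must sum to ``n_regions``; ``r_within``/``r_between``
    are the planted Pearson correlations inside and across modules;
    ``post_delta`` is the signed increment added in the post session
    (within-module pairs only, unless a custom ``pair_mask`` is given).
    ``noise_sd`` sets the marginal standard deviation of every series
    (correlations are scale-free, so it only affects amplitudes).
    """

    n_subjects: int = 12
    n_regions: int = 116
    n_timepoints: int = 214
    sampling_interval: float = 2.8
    # default planted correlations straddle the 0.3-0.7 threshold ladder so a
    # post-session increment moves edges at every threshold, not only high ones
    module_sizes: tuple[int, ...] = (29, 29, 29, 29)
    r_within: float = 0.4
    r_between: float = 0.1
    post_delta: float = 0.0
    band: tuple[float, float] = (0.01, 0.1)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_regions < 2 or self.n_timepoints < 8:
            raise ValueError("degenerate dataset dimensions")
        if sum(self.module_sizes) != self.n_regions:
            raise ValueError(
                f"module_sizes sum {sum(self.module_sizes)} != n_regions {self.n_regions}"
            )
        if not (0 <= self.r_within < 1):
            raise ValueError("r_within must lie in [0, 1)")
        if not (0 <= self.r_between <= self.r_within):
            raise ValueError("r_between must lie in [0, r_within]")
        if abs(self.r_within + self.post_delta) >= 1:
            raise ValueError("|r_within + post_delta| must be < 1")
        nyq = 0.5 / self.sampling_interval
        lo, hi = self.band
        if not (0 < lo < hi <= nyq + 1e-12):
            raise ValueError(f"band must lie within (0, {nyq:.4f}] Hz")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def module_of(self) -> np.ndarray:
        """Planted module id per region."""
        out = np.empty(self.n_regions, dtype=int)
        start = 0
        for m, size in enumerate(self.module_sizes):
            out[start : start + size] = m
            start += size
        return out

    def region_labels(self) -> tuple[str, ...]:
        width = len(str(self.n_regions))
        return tuple(f"R{i + 1:0{width}d}" for i in range(self.n_regions))


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated dataset plus its ground truth."""

    config: SyntheticConfig
    subjects: tuple[str, ...]
    series: dict  # (subject, session) -> RegionalTimeSeries
    module_of: np.ndarray
    planted_correlation: dict  # session -> (n_regions, n_regions) matrix
    psd_adjusted: dict  # session -> bool, True if PSD projection was needed

    def get(self, subject: str, session: str) -> RegionalTimeSeries:
        return self.series[(subject, session)]

    def write(self, outdir) -> None:
        """One TSV per subject-session plus a JSON sidecar with ground truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (subject, session), ts in self.series.items():
            ts.write_tsv(outdir / f"{subject}_ses-{session}_timeseries.tsv")
        sidecar = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.__dict__.items()
            },
            "subjects": list(self.subjects),
            "module_of": self.module_of.tolist(),
            "planted_correlation": {
                s: m.tolist() for s, m in self.planted_correlation.items()
            },
            "psd_adjusted": self.psd_adjusted,
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh)


def planted_correlation_matrix(config: SyntheticConfig, session: str) -> tuple[np.ndarray, bool]:
    """Target correlation matrix for one session, projected to PSD if needed.

    Returns the matrix and a flag recording whether a projection to the
    nearest positive semi-definite correlation matrix was required.
    """
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    mods = config.module_of
    same = mods[:, None] == mods[None, :]
    c = np.where(same, config.r_within, config.r_between).astype(float)
    np.fill_diagonal(c, 1.0)
    if session == "post" and config.post_delta != 0.0:
        delta = np.where(same, config.post_delta, 0.0)
        np.fill_diagonal(delta, 0.0)
        c = c + delta
    if np.any(np.abs(c - np.diag(np.diag(c))) >= 1.0):
        raise ValueError("planted off-diagonal correlations must lie in (-1, 1)")
    vals = np.linalg.eigvalsh(c)
    adjusted = False
    if vals[0] < -1e-10:
        adjusted = True
        w, v = np.linalg.eigh(c)
        c = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
    return c, adjusted


def _band_limited_noise(rng: np.random.Generator, n_regions: int, n_timepoints: int,
                        sampling_interval: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance white noise restricted to ``band`` with an ideal zero-phase filter."""
    x = rng.standard_normal((n_regions, n_timepoints))
    freqs = rfftfreq(n_timepoints, d=sampling_interval)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    spec = rfft(x, axis=1)
    spec[:, ~mask] = 0.0
    y = irfft(spec, n=n_timepoints, axis=1)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full pre/post multi-subject dataset.

    Deterministic given ``config.seed``: one global seed sequence spawns an
    independent substream per subject, and each subject stream draws the
    pre then the post session, so adding subjects never perturbs existing
    ones.
    """
    targets = {}
    adjusted = {}
    roots = {}
    for session in SESSIONS:
        c, adj = planted_correlation_matrix(config, session)
        targets[session] = c
        adjusted[session] = adj
        w, v = np.linalg.eigh(c)
        roots[session] = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T

    width = len(str(config.n_subjects))
    subjects = tuple(f"sub-{i + 1:0{width}d}" for i in range(config.n_subjects))
    labels = config.region_labels()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    series = {}
    for subj, ss in zip(subjects, streams):
        rng = np.random.default_rng(ss)
        for session in SESSIONS:
            noise = _band_limited_noise(
                rng, config.n_regions, config.n_timepoints,
                config.sampling_interval, config.band,
            )
            mixed = roots[session] @ noise
            mixed *= config.noise_sd
            series[(subj, session)] = RegionalTimeSeries(
                mixed, labels, config.sampling_interval
            )
    return SyntheticDataset(
        config=config,
        subjects=subjects,
        series=series,
        module_of=config.module_of,
        planted_correlation=targets,
        psd_adjusted=adjusted,
    )


# ---------------------------------------------------------------------------
# toy fixtures and random-graph models

def _fixture_edges() -> dict[str, tuple[int, list[tuple[int, int]]]]:
    return {
        # central node 0 with three neighbours, two of the three possible
        # neighbour pairs closed: degree 3, clustering 2/3
        "figure1_clustering": (4, [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3)]),
        "path3": (3, [(0, 1), (1, 2)]),
        "path5": (5, [(0, 1), (1, 2), (2, 3), (3, 4)]),
        "triangle": (3, [(0, 1), (1, 2), (0, 2)]),
        "star": (6, [(0, i) for i in range(1, 6)]),
        "two_cliques": (6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]),
        "complete_k4": (4, [(i, j) for i in range(4) for j in range(i + 1, 4)]),
        "complete_k5": (5, [(i, j) for i in range(5) for j in range(i + 1, 5)]),
    }


def toy_graph_names() -> tuple[str, ...]:
    return tuple(sorted(_fixture_edges()))


def make_toy_graph(name: str) -> BinaryGraph:
    """Small documented fixtures with known metric values."""
    fixtures = _fixture_edges()
    if name not in fixtures:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(fixtures))}"
        )
    n, edges = fixtures[name]
    return BinaryGraph.from_edges(n, edges)


def make_random_graph(model: str, seed: int | None = None, **params) -> BinaryGraph:
    """Classic random-graph models: erdos_renyi, watts_strogatz, ring_lattice.

    ``erdos_renyi`` takes n, p; ``watts_strogatz`` takes n, k (even), p;
    ``ring_lattice`` takes n, k (even).  Reproducible per seed.
    """
    if model == "erdos_renyi":
        n, p = int(params["n"]), float(params["p"])
        if not (0 <= p <= 1):
            raise ValueError("p must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif model == "watts_strogatz":
        n, k, p = int(params["n"]), int(params["k"]), float(params["p"])
        if k % 2 or k >= n:
            raise ValueError("lattice degree k must be even and < n")
        if not (0 <= p <= 1):
            raise ValueError("p must lie in [0, 1]")
        g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    elif model == "ring_lattice":
        n, k = int(params["n"]), int(params["k"])
        if k % 2 or k >= n:
            raise ValueError("lattice degree k must be even and < n")
        g = nx.watts_strogatz_graph(n, k, 0.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return BinaryGraph.from_edges(g.number_of_nodes(), g.edges())
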