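"""End-to-end driver: time series -> graphs -> metrics -> nulls -> comparison.

Mirrors the analysis flow of a pre/post resting-state study: wavelet
sub-band filtering of each subject-session's regional series, Pearson
adjacency, thresholding at a ladder of correlation levels, graph metrics
per subject-session-threshold, community structure and small-worldness on
the group-mean graphs, and paired Wilcoxon comparison of the two
sessions.  Every run writes a manifest with the effective configuration,
package version, per-stage wall times, and a content hash of every output
file, so a re-run with the same seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import louvain_partition, participation_coefficients
from .connectivity import (
    RegionalTimeSeries,
    correlation_matrix,
    node_strength,
    threshold_binarize,
    wavelet_subband_filter,
)
from .metrics import compute_metric_table
from .nulls import small_worldness
from .stats import compare_sessions
from .synthetic import SESSIONS, SyntheticConfig, generate_dataset

log = logging.getLogger("fcgraph")

DEFAULT_THRESHOLDS = (0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run."""

    mode: str = "synthetic"  # synthetic | timeseries
    input_dir: str | None = None  # for mode="timeseries"
    sampling_interval: float = 2.8
    band: tuple[float, float] = (0.06, 0.1)
    prefilter_band: tuple[float, float] | None = None  # optional preliminary band-pass
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_null: int = 1000
    correction: str = "bh"
    seed: int = 0
    outdir: str = "fcgraph-out"
    synthetic: SyntheticConfig | None = None
    louvain_restarts: int = 10

    def __post_init__(self) -> None:
        th = tuple(float(t) for t in self.thresholds)
        if any(not (0 < t < 1) for t in th) or any(
            b <= a for a, b in zip(th, th[1:])
        ):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")
        self.thresholds = th
        if self.mode not in ("synthetic", "timeseries"):
            raise ValueError("mode must be 'synthetic' or 'timeseries'")
        if self.mode == "timeseries" and not self.input_dir:
            raise ValueError("timeseries mode needs input_dir")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.synthetic).items()
            }
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_timeseries(config: PipelineConfig) -> dict:
    series = {}
    root = Path(config.input_dir)
    for path in sorted(root.glob("*_ses-*_timeseries.tsv")):
        stem = path.name.replace("_timeseries.tsv", "")
        subject, ses = stem.rsplit("_ses-", 1)
        if ses not in SESSIONS:
            raise ValueError(f"unknown session {ses!r} in {path.name}")
        series[(subject, ses)] = RegionalTimeSeries.read_tsv(
            path, config.sampling_interval
        )
    if not series:
        raise FileNotFoundError(f"no *_ses-*_timeseries.tsv files under {root}")
    return series


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the result bundle.

    The bundle maps stage names to in-memory results (connectivity
    matrices, long metric table, partitions, small-world results,
    comparison tables) and everything is also written under
    ``config.outdir`` together with ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    files: list[Path] = []

    def stage(name, **ctx):
        t0 = time.perf_counter()
        log.info("stage=%s %s", name, ctx)
        return lambda: stages.append(
            {"stage": name, **ctx, "seconds": round(time.perf_counter() - t0, 3)}
        )

    done = stage("load")
    if config.mode == "synthetic":
        syn = config.synthetic or SyntheticConfig(seed=config.seed)
        dataset = generate_dataset(syn)
        series = dataset.series
        dataset.write(outdir / "synthetic")
        files += sorted((outdir / "synthetic").iterdir())
    else:
        series = _load_timeseries(config)
    done()

    subjects = sorted({s for s, _ in series})
    sessions = sorted({ses for _, ses in series})

    # filter -> correlate -> strength
    done = stage("connectivity")
    conn: dict = {}
    strength: dict = {}
    for key, ts in series.items():
        if config.prefilter_band is not None:
            ts = wavelet_subband_filter(ts, config.prefilter_band, method="fft")
        filtered = wavelet_subband_filter(ts, config.band)
        cm = correlation_matrix(filtered)
        conn[key] = cm
        strength[key] = node_strength(cm)[0]
    conn_dir = outdir / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    for (subj, ses), cm in conn.items():
        p = conn_dir / f"{subj}_ses-{ses}_correlation.tsv"
        cm.write_tsv(p)
        files.append(p)
    done()

    # metrics per subject-session-threshold
    done = stage("metrics")
    long_tables = []
    for (subj, ses), cm in conn.items():
        for r in config.thresholds:
            g = threshold_binarize(cm, r)
            table = compute_metric_table(g, subject=subj, session=ses,
                                         strength=strength[(subj, ses)])
            long_tables.append(table.to_long())
    metrics_long = pd.concat(long_tables, ignore_index=True)
    p = outdir / "metrics.tsv"
    metrics_long.to_csv(p, sep="\t", index=False)
    files.append(p)
    done()

    # group-mean graphs: community structure and small-worldness
    done = stage("community")
    partitions = {}
    participation = {}
    smallworld = {}
    mean_cm = {}
    for ses in sessions:
        stack = np.stack([conn[(s, ses)].weights for s in subjects])
        labels = conn[(subjects[0], ses)].region_labels
        from .connectivity import ConnectivityMatrix

        mean_cm[ses] = ConnectivityMatrix(stack.mean(axis=0), labels)
        for r in config.thresholds:
            g = threshold_binarize(mean_cm[ses], r)
            if g.n_edges == 0:
                log.info("stage=community session=%s threshold=%s empty graph", ses, r)
                continue
            part = louvain_partition(g, seed=config.seed,
                                     n_restarts=config.louvain_restarts)
            partitions[(ses, r)] = part
            participation[(ses, r)] = participation_coefficients(g, part)
            p = outdir / f"partition_ses-{ses}_r{r}.tsv"
            part.write_tsv(p, labels=labels)
            files.append(p)
            pj = outdir / f"modules_ses-{ses}_r{r}.json"
            part.write_json(pj, labels=labels)
            files.append(pj)
    done()

    done = stage("smallworld", n_null=config.n_null)
    for ses in sessions:
        for r in config.thresholds:
            g = threshold_binarize(mean_cm[ses], r)
            if g.n_edges < 2:
                continue
            sw = small_worldness(g, n_null=config.n_null, seed=config.seed)
            smallworld[(ses, r)] = sw
            p = outdir / f"smallworld_ses-{ses}_r{r}.json"
            sw.to_json(p)
            files.append(p)
    done()

    # paired pre/post comparison
    comparisons = {}
    if set(sessions) == set(SESSIONS) and len(subjects) >= 5:
        done = stage("compare")
        pre = metrics_long[metrics_long["session"] == "pre"]
        post = metrics_long[metrics_long["session"] == "post"]
        for scope in ("global", "node"):
            res = compare_sessions(pre, post, scope=scope,
                                   correction=config.correction)
            comparisons[scope] = res
            p = outdir / f"comparison_{scope}.tsv"
            res.to_csv(p, sep="\t", index=False)
            files.append(p)
        done()

    manifest = {
        "version": __version__,
        "config": config.to_jsonable(),
        "stages": stages,
        "files": {
            str(f.relative_to(outdir)): _sha256(f) for f in sorted(set(files))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {
        "connectivity": conn,
        "strength": strength,
        "metrics": metrics_long,
        "partitions": partitions,
        "participation": participation,
        "smallworld": smallworld,
        "comparisons": comparisons,
        "manifest": manifest,
    }
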