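"""End-to-end study replica: cohort -> connectivity -> graphs -> statistics.

``run_pipeline`` sequences the whole analysis under one configuration:
for every subject and session it preprocesses the recording (channel
selection, alpha-band FIR, average reference, lesion-side flip,
rectangular windowing), estimates the windowed-MVAR dDTF adjacency,
sweeps the threshold grid computing graph metrics, classifies
supra-threshold edges by hemisphere, and finally runs the
normality-gated within-group (paired) and between-group comparisons plus
the clinical FMA summary. Everything is deterministic given the seed and
every metric is recomputable from the stored adjacency files alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import DEFAULT_EFFECT, make_cohort
from .connectivity import connectivity_from_windows, ConnectivityMatrix
from .graphs import (
    DEFAULT_TAU_GRID,
    classify_edges,
    compute_metrics,
    threshold_matrix,
)
from .preprocess import (
    DEFAULT_MONTAGE,
    EEGRecording,
    preprocess_recording,
    read_delimited_recording,
)
from .stats import SampleVector, fma_summary, independent_compare, paired_compare

logger = logging.getLogger("bcinet")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "metrics_statistics"]


@dataclass
class RunConfig:
    """Every tunable of one pipeline run; defaults are the study settings."""

    out_dir: str = "bcinet_run"
    input_dir: str | None = None          # read cohort from disk if set
    # synthetic-cohort settings (used when input_dir is None)
    n_bci: int = 8
    n_fes: int = 9
    effect: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    duration_s: float = 300.0
    fs: float = 512.0
    # analysis settings
    band: tuple[float, float] = (8.0, 13.0)
    window_s: float = 20.0
    step_s: float = 5.0
    p_max: int = 10
    order_chooser: str = "sbc"
    freq_resolution: float = 0.5
    eta_band: tuple[float, float] | None = None
    tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID
    network_tau: float = 0.0085           # threshold for edge-class maps
    density_variant: str = "headline"
    seed: int = 0

    def __post_init__(self) -> None:
        taus = tuple(self.tau_grid)
        if not taus or any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("tau grid must be nonempty and strictly ascending")
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("band must lie inside (0, fs/2)")
        self.tau_grid = taus

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Artifacts and provenance of one completed run."""

    out_dir: Path
    adjacency_paths: dict
    metrics: pd.DataFrame
    edge_classes: pd.DataFrame
    statistics: pd.DataFrame
    clinical: pd.DataFrame
    orders: dict
    warnings_log: list
    provenance: dict


def _load_cohort_from_dir(input_dir: str) -> tuple[pd.DataFrame, dict]:
    root = Path(input_dir)
    table = pd.read_csv(root / "clinical.tsv", sep="\t")
    recordings = {}
    for _, row in table.iterrows():
        for session in ("pre", "post"):
            path = root / f"{row['id']}_{session}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing recording {path}")
            recordings[(row["id"], session)] = read_delimited_recording(path)
    return table, recordings


def _write_adjacency(adj: ConnectivityMatrix, path: Path, sidecar: dict) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(adj.labels) + "\n")
        np.savetxt(fh, adj.weights, delimiter="\t", fmt="%.8g")
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected_warnings: list[str] = []

    if cfg.input_dir is not None:
        logger.info("loading cohort from %s", cfg.input_dir)
        table, recordings = _load_cohort_from_dir(cfg.input_dir)
    else:
        logger.info(
            "generating synthetic cohort (%d BCI-FES vs %d FES, seed %d)",
            cfg.n_bci, cfg.n_fes, cfg.seed,
        )
        table, recordings, _ = make_cohort(
            cfg.n_bci, cfg.n_fes, effect=cfg.effect, seed=cfg.seed,
            duration_s=cfg.duration_s, fs=cfg.fs,
        )
    table = table.sort_values("id").reset_index(drop=True)
    table.to_csv(out / "clinical.tsv", sep="\t", index=False)

    # --- per-subject connectivity -------------------------------------
    adjacency_paths: dict = {}
    adjacencies: dict = {}
    orders: dict = {}
    for (sid, session), rec in sorted(recordings.items()):
        stage_t = time.time()
        try:
            windows = preprocess_recording(
                rec, DEFAULT_MONTAGE, cfg.band, cfg.window_s, cfg.step_s
            )
            adj, selection = connectivity_from_windows(
                windows, p_max=cfg.p_max, chooser=cfg.order_chooser,
                band=cfg.band, freq_resolution=cfg.freq_resolution,
                eta_band=cfg.eta_band,
            )
        except Exception as err:
            raise RuntimeError(
                f"connectivity stage failed for subject {sid} ({session}): {err}"
            ) from err
        orders[(sid, session)] = selection.chosen_order
        path = out / f"adjacency_{sid}_{session}.tsv"
        _write_adjacency(adj, path, {
            "band": cfg.band, "window_s": cfg.window_s, "step_s": cfg.step_s,
            "order": selection.chosen_order, "chooser": cfg.order_chooser,
            "n_windows": adj.n_windows, "subject": sid, "session": session,
        })
        adjacency_paths[(sid, session)] = path
        adjacencies[(sid, session)] = adj
        logger.info(
            "connectivity %s/%s: order %d, %d windows, %.1fs",
            sid, session, selection.chosen_order, adj.n_windows,
            time.time() - stage_t,
        )

    # --- graph metrics over the threshold grid ------------------------
    import warnings as _warnings
    metric_rows = []
    for (sid, session), adj in sorted(adjacencies.items()):
        group = table.loc[table["id"] == sid, "group"].iloc[0]
        for tau in cfg.tau_grid:
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                g = threshold_matrix(adj, tau)
                m = compute_metrics(g)
            collected_warnings += [
                f"{sid}/{session} tau={tau}: {w.message}" for w in caught
            ]
            for rec_row in m.as_records():
                metric_rows.append({
                    "subject": sid, "group": group, "session": session,
                    "tau": tau, **rec_row,
                })
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    # --- group-mean networks and hemisphere edge accounting -----------
    edge_rows = []
    for group in table["group"].unique():
        sids = table.loc[table["group"] == group, "id"]
        for session in ("pre", "post"):
            mean_w = np.mean(
                [adjacencies[(sid, session)].weights for sid in sids], axis=0
            )
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                g = threshold_matrix(
                    mean_w, cfg.network_tau,
                    labels=next(iter(adjacencies.values())).labels,
                )
            classes = classify_edges(g, DEFAULT_MONTAGE)
            edge_rows.append({
                "group": group, "session": session, "tau": cfg.network_tau,
                **classes.counts, "total": classes.total,
            })
            with (out / f"edges_{group}_{session}.tsv").open("w") as fh:
                fh.write("source\ttarget\tweight\tclass\n")
                for cls_name, edges in (
                    ("ipsilesional", classes.ipsilesional),
                    ("contralesional", classes.contralesional),
                    ("other", classes.other),
                ):
                    for src, dst, w in edges:
                        fh.write(f"{src}\t{dst}\t{w:.8g}\t{cls_name}\n")
    edge_classes = pd.DataFrame(edge_rows)
    edge_classes.to_csv(out / "edge_classes.tsv", sep="\t", index=False)

    # --- statistics ---------------------------------------------------
    statistics = metrics_statistics(metrics, cfg.tau_grid)
    statistics.to_csv(out / "statistics.tsv", sep="\t", index=False)
    clinical = fma_summary(table)
    clinical.to_csv(out / "fma_summary.tsv", sep="\t", index=False)

    provenance = {
        "config_hash": cfg.config_hash(),
        "config": {k: str(v) for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "version": __version__,
        "numpy": np.__version__,
        "elapsed_s": round(time.time() - t0, 2),
        "warnings": collected_warnings,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return RunReport(
        out_dir=out,
        adjacency_paths=adjacency_paths,
        metrics=metrics,
        edge_classes=edge_classes,
        statistics=statistics,
        clinical=clinical,
        orders=orders,
        warnings_log=collected_warnings,
        provenance=provenance,
    )


def _sample(metrics: pd.DataFrame, **sel) -> SampleVector:
    sub = metrics
    for key, val in sel.items():
        sub = sub[sub[key] == val]
    sub = sub.sort_values("subject")
    return SampleVector(
        values=sub["value"].to_numpy(float), ids=tuple(sub["subject"]),
    )


def metrics_statistics(
    metrics: pd.DataFrame, tau_grid: tuple[float, ...]
) -> pd.DataFrame:
    """Within-group paired and between-group tests for every metric/tau.

    Global measures are tested as-is; node strength is tested per node.
    Degenerate samples (all differences zero) are recorded, not fatal.
    """
    rows = []
    groups = list(metrics["group"].unique())
    global_metrics = [
        "density", "clustering", "local_efficiency", "global_efficiency",
    ]
    node_labels = sorted(metrics.loc[metrics["metric"] == "strength", "node"].unique())

    def _record(comparison, group, metric, node, tau, result):
        rows.append({
            "comparison": comparison, "group": group, "metric": metric,
            "node": node, "tau": tau, "test": result.test_name,
            "statistic": result.statistic, "p": result.p,
            "n": result.n, "n2": result.n2,
            "degenerate": result.degenerate,
        })

    for tau in tau_grid:
        specs = [(m, "") for m in global_metrics]
        specs += [("strength", lab) for lab in node_labels]
        for metric, node in specs:
            base = dict(metric=metric, tau=tau)
            if node:
                base["node"] = node
            for group in groups:
                pre = _sample(metrics, session="pre", group=group, **base)
                post = _sample(metrics, session="post", group=group, **base)
                try:
                    res = paired_compare(pre, post)
                except ValueError as err:
                    logger.warning(
                        "paired test skipped (%s, %s, tau=%s): %s",
                        group, metric, tau, err,
                    )
                    continue
                _record("within", group, metric, node, tau, res)
            if len(groups) == 2:
                for session in ("pre", "post"):
                    sa = _sample(metrics, session=session, group=groups[0], **base)
                    sb = _sample(metrics, session=session, group=groups[1], **base)
                    try:
                        res = independent_compare(sa, sb)
                    except ValueError as err:
                        logger.warning(
                            "between-group test skipped (%s, tau=%s): %s",
                            metric, tau, err,
                        )
                        continue
                    _record(
                        f"between-{session}", f"{groups[0]} vs {groups[1]}",
                        metric, node, tau, res,
                    )
    return pd.DataFrame(rows)
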