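"""End-to-end orchestration: manifest-driven runs and cohort comparisons.

Two entry points:

* :func:`run_pipeline` — consume a dataset manifest written by
  :func:`quantalysis.simulate.generate_scenario` (or hand-built to the same
  schema), run detection, quantal content, pool back-extrapolation and
  variance-mean analysis per cell, and write tidy result tables.

* :func:`simulate_cohort` / :func:`assess_compartmentalization` — the
  sweep-summary-level replication harness: draw many cells per
  genotype x muscle directly from the generative model, estimate every
  quantity per cell, and run the between-genotype comparisons (PHP
  classification, pool and release-site t tests) per muscle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, quantal, rrp, simulate, varmean
from .containers import TraceRecording, TrainResponse, write_table
from .stats import two_group_test

log = logging.getLogger("quantalysis")


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    detection_threshold: float = 0.25
    refractory: float = 0.005
    evoked_window: float = 0.05
    rrp_window: tuple = rrp.DEFAULT_WINDOW
    alpha: float = 0.05
    control_genotype: str = "wild_type"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _load_trace(dataset_dir: Path, row) -> TraceRecording:
    path = dataset_dir / row["path"]
    if str(path).endswith(".h5"):
        trace = TraceRecording.from_hdf5(path)
    else:
        trace = TraceRecording.from_text(path)
    trace.metadata.setdefault("ca_mM", row["ca_mM"])
    return trace


def run_pipeline(config: RunConfig) -> dict:
    """Analyse every cell in the manifest; returns the result bundle.

    A cell is one (genotype, muscle) entry of one manifest.  Per-cell errors
    are recorded and remaining cells still run; the bundle's ``n_failed``
    reports how many failed.
    """
    manifest_path = Path(config.manifest)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError("empty manifest: nothing to analyse")
    dataset_dir = manifest_path.parent
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summaries, vm_rows, errors = [], [], []
    for (genotype, muscle), group in manifest.groupby(["genotype", "muscle"]):
        cell_id = f"{genotype}:{muscle}"
        try:
            summaries.append(
                _analyse_cell(cell_id, genotype, muscle, group, dataset_dir,
                              config, vm_rows))
        except Exception as exc:   # keep going; report at the end
            log.error("cell %s failed: %s", cell_id, exc)
            errors.append(dict(cell_id=cell_id, error=str(exc)))

    cells = pd.DataFrame(summaries)
    run_meta = dict(seed=config.seed, manifest=str(manifest_path),
                    parameters=json.dumps(
                        {k: str(v) for k, v in vars(config).items()},
                        sort_keys=True))
    write_table(cells, out / "cells.tsv", run_meta)
    write_table(pd.DataFrame(vm_rows), out / "variance_mean_points.tsv",
                run_meta)
    if errors:
        write_table(pd.DataFrame(errors), out / "errors.tsv", run_meta)
    with open(out / "run_log.json", "w") as fh:
        json.dump(dict(run_meta, n_cells=len(summaries),
                       n_failed=len(errors)), fh, indent=1)
    return dict(cells=cells, vm_points=pd.DataFrame(vm_rows),
                n_failed=len(errors), out_dir=str(out))


def _analyse_cell(cell_id, genotype, muscle, group, dataset_dir, config,
                  vm_rows) -> dict:
    row = dict(cell_id=cell_id, genotype=genotype, muscle=muscle)

    # --- minis --------------------------------------------------------
    spont = group[group["kind"] == "spont"]
    mepsp_mean = np.nan
    if len(spont):
        trace = _load_trace(dataset_dir, spont.iloc[0])
        events = detect.detect_minis(trace, threshold=config.detection_threshold,
                                     refractory=config.refractory)
        if len(events) == 0:
            raise ValueError("no spontaneous events detected")
        mepsp_mean = events["amplitude"].mean()
        row.update(mepsp_mean=mepsp_mean, n_minis=len(events))

    # --- evoked at the baseline condition -> quantal content ----------
    base = group[group["kind"] == "baseline"]
    if len(base) and np.isfinite(mepsp_mean):
        amps = _evoked_amplitudes(base, dataset_dir, config)
        row.update(epsp_mean=amps.mean(), n_evoked=amps.size,
                   quantal_content=quantal.quantal_content(
                       amps.mean(), mepsp_mean))

    # --- variance-mean over the Ca titration --------------------------
    evoked = group[group["kind"] == "evoked"]
    if len(evoked):
        points = []
        for ca, sweeps in evoked.groupby("ca_mM"):
            amps = _evoked_amplitudes(sweeps, dataset_dir, config)
            pt = varmean.summarize_condition(amps, ca, cell_id=cell_id)
            points.append(pt)
            vm_rows.append(dict(cell_id=cell_id, ca_mM=ca,
                                mean_amp=pt.mean_amp, variance=pt.variance,
                                n_sweeps=pt.n_sweeps))
        fit = varmean.fit_parabola(varmean.with_origin(points),
                                   cell_id=cell_id)
        row.update(quantal_size_Q=fit.quantal_size_Q,
                   n_sites_N=fit.n_sites_N,
                   vm_curvature=1.0 / fit.n_sites_N,
                   vm_rss=fit.rss,
                   vm_flags=";".join(fit.flags))

    # --- pool back-extrapolation --------------------------------------
    train_rows = group[group["kind"] == "train"]
    if len(train_rows) and np.isfinite(mepsp_mean):
        trow = train_rows.iloc[0]
        trace = _load_trace(dataset_dir, trow)
        stim = trace.stim_times
        freq = 1.0 / np.median(np.diff(stim))
        amps = detect.measure_evoked(trace, window=1.0 / freq,
                                     baseline_window=0.002)
        train = TrainResponse(amplitudes=amps["amplitude"].to_numpy(),
                              freq=freq, ca_mM=trow["ca_mM"], cell_id=cell_id)
        est = rrp.estimate_rrp(train, mepsp_mean, window=config.rrp_window)
        row.update(rrp_quanta=est.rrp_quanta, rrp_r2=est.r_squared,
                   rrp_negative_intercept=est.negative_intercept)
    return row


def _evoked_amplitudes(rows, dataset_dir, config) -> np.ndarray:
    amps = []
    for _, r in rows.iterrows():
        trace = _load_trace(dataset_dir, r)
        table = detect.measure_evoked(trace, window=config.evoked_window)
        amps.extend(table["amplitude"].tolist())
    return np.asarray(amps)


# --------------------------------------------------------------------------
# cohort-level harness (sweep-summary resolution, many cells per genotype)
# --------------------------------------------------------------------------

def simulate_cohort(scenario: simulate.ScenarioConfig, n_cells: int,
                    rng: np.random.Generator, n_minis: int = 120
                    ) -> pd.DataFrame:
    """Estimate all per-cell quantities for ``n_cells`` cells per muscle.

    Works at the per-sweep amplitude level (the estimators' native inputs);
    trace synthesis and event detection are exercised separately by
    :func:`run_pipeline`.
    """
    rows = []
    for muscle, (model, pool) in sorted(scenario.muscles.items()):
        for c in range(n_cells):
            minis = simulate.draw_quantal_sizes(rng, model.q_mean,
                                                model.q_cv, n_minis)
            mepsp = minis.mean()
            evoked = simulate.draw_evoked_amplitudes(
                model, scenario.baseline_ca, scenario.n_sweeps_per_level,
                rng=rng)
            qc = quantal.quantal_content(evoked.mean(), mepsp)

            train = simulate.simulate_train(
                model, pool, scenario.train_ca, n_stim=scenario.train_n,
                freq=scenario.train_freq, rng=rng)
            pool_est = rrp.estimate_rrp(train, mepsp)

            points = [varmean.summarize_condition(
                simulate.draw_evoked_amplitudes(
                    model, ca, scenario.n_sweeps_per_level, rng=rng), ca)
                for ca in scenario.ca_levels]
            try:
                fit = varmean.fit_parabola(varmean.with_origin(points))
                Q_hat, N_hat = fit.quantal_size_Q, fit.n_sites_N
                curv = 1.0 / fit.n_sites_N
            except varmean.UnidentifiableNError:
                # rare sampling accident (~1% of cells at 30 sweeps): the
                # sample points carry no curvature; N is unreportable but
                # the zero curvature estimate itself is still data
                Q_hat, N_hat, curv = np.nan, np.nan, 0.0

            rows.append(dict(
                genotype=scenario.label, muscle=muscle,
                cell_id=f"{scenario.label}:{muscle}:{c}",
                mepsp_mean=mepsp, epsp_mean=evoked.mean(),
                quantal_content=qc, n_minis=n_minis,
                n_evoked=scenario.n_sweeps_per_level,
                rrp_quanta=pool_est.rrp_quanta,
                quantal_size_Q=Q_hat,
                n_sites_N=N_hat,
                vm_curvature=curv))
    return pd.DataFrame(rows)


def assess_compartmentalization(test: pd.DataFrame, control: pd.DataFrame,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Per-muscle genotype comparison: PHP flag plus pool and N elevation.

    Returns one row per muscle with ``php_expressed`` (mini reduced, evoked
    maintained, quantal content increased), ``rrp_elevated`` and
    ``n_sites_elevated`` (one t test each at alpha).  The release-site
    comparison is made on the fitted parabola curvature 1/N rather than on
    N itself: the curvature is the linear least-squares coefficient and is
    approximately normal across cells, whereas its reciprocal N is heavily
    right-tailed (elevated N appears as significantly *reduced* curvature).
    """
    out = []
    for muscle in sorted(set(test["muscle"])):
        t = test[test["muscle"] == muscle]
        c = control[control["muscle"] == muscle]
        cells_t = [_row_summary(r) for _, r in t.iterrows()]
        cells_c = [_row_summary(r) for _, r in c.iterrows()]
        report = quantal.php_assessment(cells_t, cells_c, alpha=alpha)

        def shifted(col, direction=1):
            res = two_group_test(t[col].dropna(), c[col].dropna(), label=col)
            diff = res.group_means[0] - res.group_means[1]
            return bool(res.p_value < alpha and direction * diff > 0)

        out.append(dict(
            muscle=muscle,
            php_expressed=report.php_expressed,
            epsp_maintained=report.epsp_maintained,
            normalized_mepsp_pct=report.normalized_mepsp_pct,
            normalized_qc_pct=report.normalized_qc_pct,
            rrp_elevated=shifted("rrp_quanta"),
            n_sites_elevated=shifted("vm_curvature", direction=-1)))
    return pd.DataFrame(out)


def _row_summary(r) -> quantal.QuantalSummary:
    return quantal.QuantalSummary(
        cell_id=r["cell_id"], muscle=r["muscle"], genotype=r["genotype"],
        mepsp_mean=r["mepsp_mean"], epsp_mean=r["epsp_mean"],
        n_minis=int(r["n_minis"]), n_evoked=int(r["n_evoked"]), mode="tevc")
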