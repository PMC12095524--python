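"""End-to-end driver: simulate -> calibrate -> featurize -> forward/reverse
models -> history classification -> report.

All inter-stage data are flat delimited tables plus JSON metadata so other
ecosystems can consume intermediates.  Each table carries a comment header
with a units note and the configuration hash; read them back with
``pandas.read_csv(..., comment="#")``.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import classify as cls
from . import features as feat
from . import forward as fwd
from . import reverse as rev
from . import simulate as sim
from . import stats as st
from .config import RunConfig

log = logging.getLogger("erkdyn")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def write_table(df: pd.DataFrame, path: Path, units: str, config_hash: str,
                index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {units}; config_hash: {config_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic data; returns the summary report."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    report: dict = {"config_hash": h, "seed": config.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                t0 = time.time()
                out = fn()
                report["stages"][name] = {"ok": True, "seconds": round(time.time() - t0, 2)}
                log.info("stage %s done in %.1fs", name, time.time() - t0)
                return out
            except Exception as exc:
                report["stages"][name] = {"ok": False, "error": str(exc)}
                raise StageError(name, exc) from exc
        return deco

    @stage("simulate")
    def dataset():
        sc = config.simulate
        layout = sim.default_layout(n_cells_per_well=sc.n_cells_per_well,
                                    replicates=sc.replicates)
        simcfg = sim.SimConfig(noise_cv=sc.noise_cv,
                               clustered_fraction=sc.clustered_fraction,
                               batch_log10_sd=sc.batch_log10_sd,
                               ode_dt=sc.ode_dt)
        ds = sim.generate_dataset(layout, simcfg, seed=config.seed)
        ds.to_dir(outdir)
        return ds

    ds = dataset

    @stage("calibrate")
    def calibrated():
        cc = config.calibration
        true = cal.CalibrationParams(cc.k_au, cc.k_ap, cc.r_p)
        rng = np.random.default_rng(config.seed + 1)
        # synthetic phos-tag anchors at graded phospho fractions
        ps = np.linspace(0.0, 1.0, 6)
        pts = [cal.PhosTagPoint(p, float(np.clip(
            cal.activity_to_fa(p / max(1e-9, (1 - p)), true) if p < 1 else cc.k_ap,
            0, 1) + rng.normal(0, cc.fa_noise_sd))) for p in ps]
        fitted = cal.fit_calibration(pts, r_p=cc.r_p)
        # round-trip the simulated activity through the fitted calibration
        fa = cal.activity_to_fa(ds.traces, true)
        traces_cal = cal.fa_to_activity(fa, fitted)
        corrected, scalings = cal.batch_correct(
            ds.stains, ds.cells.set_index("cell_id").loc[ds.stains.index],
            reference_replicate=sorted(ds.cells["replicate"].unique())[0])
        (outdir / "calibration.json").write_text(json.dumps({
            "true": {"k_au": true.k_au, "k_ap": true.k_ap, "r_p": true.r_p},
            "fitted": {"k_au": fitted.k_au, "k_ap": fitted.k_ap, "r_p": fitted.r_p},
            "batch_scalings": [vars(s) for s in scalings],
        }, indent=1, default=str))
        write_table(corrected, outdir / "stains_corrected.csv",
                    "arbitrary fluorescence intensity (linear scale)", h, index=True)
        return traces_cal, corrected

    traces_cal, stains_corr = calibrated

    @stage("featurize")
    def features_tbl():
        keep = feat.qc_filter(traces_cal, ds.t_min, min_hours=config.features.min_hours)
        prom = feat.default_prominence(traces_cal[keep],
                                       config.features.min_prominence_fraction)
        table = feat.featurize_table(traces_cal[keep], ds.t_min, min_prominence=prom,
                                     cell_ids=ds.cells.loc[keep, "cell_id"])
        write_table(table.reset_index(), outdir / "features.csv",
                    "activity dimensionless; durations/intervals min; frequency cycles/h",
                    h)
        return keep, table

    keep, features_tbl_ = features_tbl
    X = traces_cal[keep]
    cells_k = ds.cells.loc[keep].reset_index(drop=True)
    stains_k = stains_corr.loc[cells_k["cell_id"]]

    @stage("forward")
    def forward_metrics():
        fc = config.forward
        strata = cells_k["condition"].to_numpy()
        splits = fwd.make_splits(strata, n_folds=fc.n_folds, seed=config.seed)
        target = np.log10(stains_k[fc.target].to_numpy())
        Xf = X
        offset = 0
        if fc.keep_last_n:
            Xf, offset = fwd.truncate_window(X, fc.keep_last_n)
        rows = []
        _, m_ts = fwd.fit_ts_linear(Xf, target, splits)
        rows.append(m_ts.assign(model="ts_linear"))
        _, m_fl = fwd.fit_featurized_linear(
            features_tbl_[feat.FEATURE_NAMES], target, splits)
        rows.append(m_fl.assign(model="feat_linear"))
        if fc.cnn:
            models, m_cnn = fwd.fit_cnn(
                Xf, target, splits[:1], epochs=fc.epochs, lr=fc.lr, l2=fc.l2,
                batch_size=fc.batch_size)
            rows.append(m_cnn.assign(model="cnn"))
            amap = fwd.attribute(models[0], Xf, n_steps=fc.attribution_steps,
                                 window_offset=offset)
            att = pd.DataFrame({"timepoint": np.arange(len(amap.mean)) + offset,
                                "attribution": amap.mean})
            write_table(att, outdir / "attribution.csv",
                        "integrated gradients, standardized model units", h)
        metrics = pd.concat(rows, ignore_index=True)
        write_table(metrics, outdir / "forward_metrics.csv",
                    "R2 and MSE on log10 stain intensity", h)
        return metrics

    forward_metrics_ = forward_metrics

    @stage("reverse")
    def reverse_metrics():
        rc = config.reverse
        rows, models = [], {}
        for fname in feat.FEATURE_NAMES:
            y = features_tbl_[fname].to_numpy()
            mlr = rev.fit_mlr(stains_k, y, fname, folds=rc.folds, seed=config.seed,
                              log_scale=rc.log_scale)
            rows.append({"feature": fname, "predictor_set": "all", "r2": mlr.r2,
                         "rmse": mlr.rmse})
            models[fname] = mlr
            best_single = max(
                (rev.fit_single(stains_k, t, y, fname, folds=rc.folds,
                                seed=config.seed, log_scale=rc.log_scale)
                 for t in stains_k.columns), key=lambda r: r.r2)
            rows.append({"feature": fname,
                         "predictor_set": best_single.predictors[0],
                         "r2": best_single.r2, "rmse": best_single.rmse})
            ca = rev.condition_average_model(
                stains_k, y, cells_k["condition"], fname, log_scale=rc.log_scale)
            rows.append({"feature": fname, "predictor_set": "condition_average",
                         "r2": ca.r2, "rmse": ca.rmse})
        metrics = pd.DataFrame(rows)
        write_table(metrics, outdir / "reverse_metrics.csv",
                    "R2/RMSE of dynamic-feature regressions", h)
        (outdir / "reverse_models.json").write_text(json.dumps({
            f: {"predictors": m.predictors,
                "coefficients": m.coefficients.tolist(),
                "intercept": m.intercept, "r2": m.r2}
            for f, m in models.items()}, indent=1))
        return metrics

    reverse_metrics_ = reverse_metrics

    @stage("classify")
    def classify_report():
        cc = config.classify
        res = cls.regional_pipeline(
            X, stains_k, cells_k, radius_um=cc.hex_radius_um, k=cc.k,
            seed=config.seed, r_min=cc.r_min, n_rounds=cc.n_rounds,
            folds=cc.folds, min_cells_per_class=cc.min_cells_per_class,
            groups=cells_k["well"].to_numpy())
        proto = res["prototypes"]
        write_table(pd.DataFrame(proto.centroids,
                                 columns=[f"t{j}" for j in range(proto.centroids.shape[1])]),
                    outdir / "prototypes.csv", "centroid ERK activity", h)
        classes = pd.DataFrame({"cell_id": cells_k["cell_id"],
                                "class": proto.labels,
                                "correlation": proto.correlation,
                                "kept": proto.kept})
        write_table(classes, outdir / "classes.csv", "history class 1..k", h)
        preds = pd.Series(res["single_cell"].predict(stains_k),
                          index=cells_k["cell_id"])
        overlay = cls.annotate(preds, cells_k)
        write_table(overlay, outdir / "overlay.csv", "um coordinates, class colors", h)
        imp = cls.predictor_importance(res["single_cell"])
        rep = {
            "single_cell_accuracy": res["single_cell_accuracy"],
            "regional_accuracy": res["regional_accuracy"],
            "n_regions": res["n_regions"],
            "radius_um": res["radius_um"],
            "predictor_importance": imp.to_dict(),
            "confusion": res["single_cell"].confusion.to_dict(),
        }
        (outdir / "classifier_report.json").write_text(json.dumps(rep, indent=1))
        return rep

    classify_report_ = classify_report

    @stage("stats")
    def stats_tbl():
        cond = cells_k["condition"].to_numpy()
        reps = cells_k["replicate"].to_numpy()
        ctrl = cond == "EGF0@0"
        high = cond == "EGF100@0"
        rows = []
        for target in stains_k.columns:
            v = np.log10(stains_k[target].to_numpy())
            res = st.variance_corrected_ttest(v[high], reps[high], v[ctrl], reps[ctrl])
            rows.append({"target": target, "t": res.t, "p": res.p, "df": res.df})
        tbl = pd.DataFrame(rows)
        rej, padj = st.bh_fdr(tbl["p"].to_numpy(), alpha=config.stats.alpha)
        tbl["p_adj"] = padj
        tbl["significant"] = rej
        write_table(tbl, outdir / "stats.csv",
                    "variance-corrected t-test, log10 intensities, BH-adjusted", h)
        return tbl

    stats_tbl_ = stats_tbl

    report["n_cells"] = int(ds.n_cells)
    report["n_kept"] = int(keep.sum())
    report["elapsed_seconds"] = round(time.time() - t_start, 1)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    lines = [f"erkdyn pipeline report (config {h}, seed {config.seed})",
             f"cells simulated: {ds.n_cells}, kept after QC: {int(keep.sum())}"]
    lines += [f"  {k}: {'ok' if v['ok'] else 'FAILED'} ({v.get('seconds', '-')}s)"
              for k, v in report["stages"].items()]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
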