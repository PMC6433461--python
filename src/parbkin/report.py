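"""Pipeline orchestration and between-condition statistics.

``run_pipeline`` drives the full chain — simulate molecules (optionally
rendering and re-quantifying image stacks), segment traces into phases,
fit rates per molecule, aggregate per condition, compare conditions with
pairwise Student's t-tests — and writes tables, plots and a reproducible
run log.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import imagequant, kinetics, render
from .schedule import SwitchingSchedule
from .simulate import KineticModel, SimulationTruth, run_protocol
from .trace import IntensityTrace

__all__ = ["PValueMatrix", "PipelineError", "ttest_matrix", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PValueMatrix:
    """Symmetric matrix of pairwise two-sample p-values with unit diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be square with one row per label")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def ttest_matrix(groups: dict[str, list[float]], equal_var: bool = True) -> PValueMatrix:
    """Pairwise two-sided two-sample t-test p-values between condition groups.

    Equal-variance (Student's) by default; ``equal_var=False`` gives
    Welch's test.  The diagonal is 1.  Groups with fewer than 2 values are
    reported as missing (NaN row/column).
    """
    labels = list(groups)
    n = len(labels)
    mat = np.full((n, n), np.nan)
    for i, a in enumerate(labels):
        if len(groups[a]) >= 2:
            mat[i, i] = 1.0
        for j in range(i + 1, n):
            b = labels[j]
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                continue
            if np.array_equal(groups[a], groups[b]):
                p = 1.0  # identical samples: t = 0 by construction
            else:
                p = float(stats.ttest_ind(groups[a], groups[b],
                                          equal_var=equal_var).pvalue)
            mat[i, j] = mat[j, i] = p
    return PValueMatrix(labels=labels, matrix=mat)


# ----------------------------------------------------------------------
# pipeline


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _simulate_condition(cond: dict, sim_cfg: dict, sched_cfg: dict,
                        rng: np.random.Generator,
                        render_stacks: bool) -> list[IntensityTrace]:
    """Simulate (and optionally render + re-quantify) one condition's molecules."""
    truth_cfg = dict(sim_cfg.get("truth", {}))
    model = KineticModel(kon=float(truth_cfg.pop("kon")),
                         koff=float(truth_cfg.pop("koff")))
    truth = SimulationTruth(model=model, **truth_cfg)
    conc = float(cond["concentration_nM"]) * 1e-9
    n_mol = int(cond.get("n_molecules", 10))
    period = float(sched_cfg.get("period", 60.0))
    tau = float(sched_cfg.get("exchange_time", 6.5))
    n_cycles = int(sched_cfg.get("n_cycles", 2))
    brightness = float(sim_cfg.get("brightness", 100.0))
    noise_sd = float(sim_cfg.get("noise_sd", 0.0))

    traces = []
    for i in range(n_mol):
        mol_id = f"{cond['label']}_c{cond['concentration_nM']}nM_m{i:02d}"
        traj, trace = run_protocol(truth, "switching", concentration=conc,
                                   period=period, n_cycles=n_cycles,
                                   exchange_time=tau, brightness=brightness,
                                   noise_sd=noise_sd, molecule_id=mol_id, rng=rng)
        if render_stacks:
            optics = render.Optics()
            stack = render.render_stack(traj, optics, rng=rng)
            x0 = max(0, int(optics.dna_start[0]) - 3)
            x1 = min(optics.shape[1], int(math.ceil(optics.dna_end[0])) + 3)
            y = int(optics.dna_start[1])
            main = imagequant.ROI(x0, x1, y - 4, y + 4)
            rois = imagequant.ROISet.around(main, optics.shape, gap=1)
            trace = imagequant.extract_trace(stack, rois, truth.frame_rate,
                                             molecule_id=mol_id)
        traces.append(trace)
    return traces


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int = 0) -> dict:
    """Run the full analysis described by ``config`` and write a report bundle.

    Returns a dict with the per-molecule fit table, condition summaries,
    the kon estimate, and the koff p-value matrix.  Outputs written to
    ``out_dir``: ``fits.csv``, ``summary.csv``, ``pvalues_koff.csv``,
    ``kon.json``, ``run_log.json`` and diagnostic plots.  The same config
    and seed reproduce the tables byte for byte.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)

    # ---- simulate / load traces ----
    try:
        sim_cfg = cfg.get("simulation")
        sched_cfg = cfg.get("schedule", {})
        per_condition: dict[tuple[str, float], list[IntensityTrace]] = {}
        if sim_cfg is not None:
            for cond in sim_cfg["conditions"]:
                traces = _simulate_condition(cond, sim_cfg, sched_cfg, master,
                                             bool(cfg.get("render", False)))
                per_condition[(cond["label"], float(cond["concentration_nM"]))] = traces
        else:
            traces_cfg = cfg.get("traces")
            if not traces_cfg:
                raise PipelineError("[input] no simulation block and no trace files")
            for entry in traces_cfg:
                paths = sorted(Path(entry["dir"]).glob("*.csv"))
                if not paths:
                    raise PipelineError(f"[input] no trace CSVs in {entry['dir']}")
                per_condition[(entry["label"], float(entry["concentration_nM"]))] = [
                    IntensityTrace.from_csv(p) for p in paths]
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise PipelineError(f"[simulate] {exc}") from exc

    # ---- segment + fit ----
    try:
        period = float(sched_cfg.get("period", 60.0))
        tau = float(sched_cfg.get("exchange_time", 6.5))
        dead_time = float(cfg.get("fit", {}).get("dead_time_s", tau))
        rows = []
        fits_by_key: dict[tuple[str, float, str], list[kinetics.KineticFit]] = {}
        for (label, conc_nM), traces in per_condition.items():
            sched = SwitchingSchedule.square_wave(conc_nM * 1e-9, period=period,
                                                  exchange_time=tau)
            for trace in traces:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    windows = kinetics.segment_cycles(trace, sched, dead_time=dead_time)
                for w in windows:
                    fit = kinetics.fit_phase(trace, w)
                    fits_by_key.setdefault((label, conc_nM, w.kind), []).append(fit)
                    rows.append({
                        "molecule_id": trace.molecule_id, "condition": label,
                        "concentration_nM": conc_nM, "phase": w.kind,
                        "rate_s^-1": fit.rate, "stderr": fit.stderr,
                        "amplitude": fit.amplitude, "rss": fit.rss,
                        "n_points": fit.n_points,
                        "flags": fit.flag,
                    })
        fits_df = pd.DataFrame(rows)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[fit] {exc}") from exc

    # ---- aggregate ----
    try:
        summaries = []
        for (label, conc_nM, kind), fits in sorted(fits_by_key.items()):
            # one rate per molecule first (mean over that molecule's phases)
            per_mol: dict[str, list[float]] = {}
            for f in fits:
                if f.ok:
                    per_mol.setdefault(f.molecule_id, []).append(f.rate)
            mol_rates = [float(np.mean(v)) for v in per_mol.values()]
            if not mol_rates:
                continue
            sd = float(np.std(mol_rates, ddof=1)) if len(mol_rates) > 1 else 0.0
            summaries.append({
                "condition": label, "concentration_nM": conc_nM, "phase": kind,
                "mean_rate_s^-1": float(np.mean(mol_rates)), "sd_rate_s^-1": sd,
                "n_molecules": len(mol_rates),
            })
        summary_df = pd.DataFrame(summaries)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[aggregate] {exc}") from exc

    # ---- kon from the low-concentration kobs points ----
    kon_results = {}
    try:
        n_low = int(cfg.get("fit", {}).get("n_low", 2))
        for label in {k[0] for k in fits_by_key}:
            pts = [(row["concentration_nM"] * 1e-9, row["mean_rate_s^-1"])
                   for row in summaries
                   if row["condition"] == label and row["phase"] == "association"]
            if len(pts) >= n_low:
                est = kinetics.estimate_kon(pts, n_low=n_low)
                kon_results[label] = {"kon_M^-1s^-1": est.kon,
                                      "koff_intercept_s^-1": est.koff_intercept}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[kon] {exc}") from exc

    # ---- between-condition statistics on koff ----
    try:
        groups: dict[str, list[float]] = {}
        for (label, conc_nM, kind), fits in sorted(fits_by_key.items()):
            if kind != "dissociation":
                continue
            groups.setdefault(label, []).extend(f.rate for f in fits if f.ok)
        pmat = ttest_matrix(groups) if len(groups) >= 1 else None
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[stats] {exc}") from exc

    # ---- write bundle ----
    try:
        fits_df.to_csv(out / "fits.csv", index=False, float_format="%.8g")
        summary_df.to_csv(out / "summary.csv", index=False, float_format="%.8g")
        if pmat is not None:
            pmat.to_frame().to_csv(out / "pvalues_koff.csv", float_format="%.8g")
        with open(out / "kon.json", "w") as fh:
            json.dump(kon_results, fh, indent=2, sort_keys=True)
        log = {"seed": seed, "config_hash": _config_hash(cfg),
               "n_conditions": len(per_condition),
               "n_traces": int(sum(len(v) for v in per_condition.values()))}
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        _write_plots(out, per_condition, summary_df)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[report] {exc}") from exc

    return {"fits": fits_df, "summary": summary_df, "kon": kon_results,
            "pvalues_koff": pmat, "log": log}


def _write_plots(out: Path, per_condition, summary_df: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # representative trace
    (label, conc), traces = next(iter(per_condition.items()))
    fig, ax = plt.subplots(figsize=(6, 3))
    tr = traces[0]
    ax.plot(tr.times, tr.values, lw=0.7, color="crimson")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (counts)")
    ax.set_title(f"{label}, {conc:g} nM — {tr.molecule_id}")
    fig.tight_layout()
    fig.savefig(out / "trace_example.png", dpi=120)
    plt.close(fig)

    # kobs vs concentration
    assoc = summary_df[summary_df["phase"] == "association"]
    if len(assoc):
        fig, ax = plt.subplots(figsize=(4, 3))
        for label, sub in assoc.groupby("condition"):
            sub = sub.sort_values("concentration_nM")
            ax.errorbar(sub["concentration_nM"], sub["mean_rate_s^-1"],
                        yerr=sub["sd_rate_s^-1"], marker="o", capsize=3, label=label)
        ax.set_xlabel("[protein] (nM)")
        ax.set_ylabel(r"$k_{obs}$ (s$^{-1}$)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "kobs_vs_concentration.png", dpi=120)
        plt.close(fig)
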