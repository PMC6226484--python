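"""End-to-end orchestration: simulate/load -> segment -> fit -> scan -> report.

A run is described by a flat YAML/JSON config; outputs are a tabular results
file (TSV: condition, model, parameter, estimate, stderr, flags), scan curves,
transition lists and a log with the config hash, all deterministic for a given
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import likelihood as lk
from . import segmentation as seg
from . import synthetic as syn
from .models import BlinkParams, TCParams, TwoStateParams, association_rate_coefficient, make_two_state
from .trajectory import read_phot_tsv

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_PARTIAL = 1
EXIT_BAD_CONFIG = 2


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sim_config_from(cfg: dict, seed: int) -> syn.SimConfig:
    two = TwoStateParams(
        E_B=cfg["E_B"], E_U=cfg["E_U"], k_A_app=cfg["k_A_app"], k_D=cfg["k_D"]
    )
    tc = None
    if "t_TC" in cfg:
        tc = TCParams.from_lifetime(cfg["t_TC"], cfg.get("E_TC", 0.5 * (two.E_B + two.E_U)))
    blink = None
    if cfg.get("blink"):
        b = cfg["blink"]
        blink = BlinkParams(
            E_d=b.get("E_d", 0.06), k_b=b.get("k_b", 3000.0), k_0=b.get("k_0", 500.0)
        )
    return syn.SimConfig(
        two=two,
        tc=tc,
        blink=blink,
        rate_ms=cfg.get("rate_ms", 100.0),
        duration_s=cfg.get("duration_s", 1.0),
        k_bleach_acceptor=cfg.get("k_bleach_acceptor", 0.0),
        k_bleach_donor=cfg.get("k_bleach_donor", 0.0),
        n_traj=cfg.get("n_traj", 10),
        seed=seed,
        label=cfg.get("label", "sim"),
    )


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the configured analysis; returns results and writes artifacts.

    Returns a dict with keys ``table`` (DataFrame), ``status`` (exit code),
    ``scan`` (LifetimeScan or None) and ``report`` (human-readable summary).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    mode = cfg.get("mode", "idp")
    rows = []
    status = EXIT_OK
    scan_obj = None
    chash = config_hash(cfg)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    log.info("run config hash %s seed %s mode %s", chash, seed, mode)

    try:
        # ---- inputs
        if "simulate" in cfg:
            sim_cfg = _sim_config_from(cfg["simulate"], seed)
            trajs = syn.simulate_ctmc_photons(sim_cfg)
            condition = sim_cfg.label
            truth = dataclasses.asdict(sim_cfg.two)
            (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        elif "photons" in cfg:
            trajs = []
            for f in cfg["photons"]:
                trajs.extend(read_phot_tsv(f))
            condition = cfg.get("condition", "data")
        else:
            raise KeyError("config needs 'simulate' or 'photons'")

        conc = cfg.get("partner_conc_M")

        # ---- equilibrium fit
        fit_cfg = cfg.get("fit", {})
        model_kind = fit_cfg.get("model", "two")
        fix_pB = None
        if mode == "folded" or fit_cfg.get("fix_pB_from_start"):
            e_b0 = fit_cfg.get("E_B_guess", 0.75)
            e_u0 = fit_cfg.get("E_U_guess", 0.06)
            fix_pB = lk.estimate_pB_from_start(trajs, e_b0, e_u0)
            fix_pB = min(max(fix_pB, 0.01), 0.99)
            rows.append((condition, "start-state", "p_B", fix_pB, np.nan, "counting"))
        if model_kind == "four":
            fit = lk.fit_four_state(trajs, seed=seed)
        else:
            fit = lk.fit_two_state(trajs, fix_pB=fix_pB, seed=seed)
        for name, val in fit.params.items():
            rows.append(
                (condition, model_kind + "-state", name, val, fit.stderr.get(name, np.nan), "")
            )
        if conc:
            k_a = association_rate_coefficient(fit.params["k_A_app"], conc)
            rows.append((condition, model_kind + "-state", "k_A", k_a, np.nan, "per-molar"))
        if not fit.convergence:
            status = EXIT_PARTIAL

        # ---- segmentation + lifetime scan
        scan_cfg = cfg.get("scan", {})
        if scan_cfg.get("enabled", True):
            base = TwoStateParams(
                fit.params["E_B"], fit.params["E_U"],
                fit.params["k_A_app"], fit.params["k_D"],
            )
            vit_model = make_two_state(base)
            seg_cfg = cfg.get("segmentation", {})
            min_res = seg_cfg.get("min_residence", seg.MIN_RESIDENCE)
            window = seg_cfg.get("window_total", seg.WINDOW_TOTAL)
            segments = []
            all_transitions = []
            for tr in trajs:
                path = seg.viterbi_path(tr, vit_model)
                transitions = seg.find_transitions(tr, path, min_res)
                all_transitions.extend(transitions)
                if mode == "folded":
                    transitions = seg.first_event_only(transitions)
                segments.extend(seg.extract_segments(tr, transitions, window))
            pd.DataFrame(
                [
                    (t.traj_id, t.time, t.direction, t.left_dwell, t.right_dwell)
                    for t in all_transitions
                ],
                columns=["trajectory_id", "time_s", "direction", "left_dwell_s", "right_dwell_s"],
            ).to_csv(out / "transitions.tsv", sep="\t", index=False)

            if segments:
                blink = None
                if scan_cfg.get("blink"):
                    b = scan_cfg["blink"]
                    blink = BlinkParams(
                        E_d=b.get("E_d", 0.06), k_b=b.get("k_b", 3000.0), k_0=b.get("k_0", 500.0)
                    )
                t_grid = np.geomspace(
                    scan_cfg.get("t_min", 0.5e-6),
                    scan_cfg.get("t_max", 10e-3),
                    int(scan_cfg.get("n_points", 50)),
                )
                scan_obj = lk.delta_lnL_scan(
                    segments, base, blink=blink, t_grid=t_grid,
                    E_TC_mode=scan_cfg.get("E_TC_mode", "fixed-midpoint"),
                )
                pd.DataFrame(
                    {"t_TC_s": scan_obj.t_grid, "delta_lnL": scan_obj.delta_lnL}
                ).to_csv(out / "scan.tsv", sep="\t", index=False)
                r = scan_obj.result
                if r.significant:
                    rows.append((condition, "tc-scan", "t_TC", r.t_hat, r.t_stderr, "peak>+3"))
                elif r.upper_bound is not None:
                    rows.append(
                        (condition, "tc-scan", "t_TC_upper_bound", r.upper_bound, np.nan,
                         "upper_bound")
                    )
                else:
                    rows.append((condition, "tc-scan", "t_TC", np.nan, np.nan, r.note))
            else:
                log.warning("no transition segments found; scan skipped")
                status = EXIT_PARTIAL
    except Exception:
        log.exception("pipeline stage failed; partial outputs retained")
        status = EXIT_PARTIAL
        raise
    finally:
        table = pd.DataFrame(
            rows, columns=["condition", "model", "parameter", "estimate", "stderr", "flags"]
        )
        table.to_csv(out / "results.tsv", sep="\t", index=False)
        log.removeHandler(fh)
        fh.close()

    summary = report(table, conc)
    (out / "report.txt").write_text(summary)
    return {"table": table, "status": status, "scan": scan_obj, "report": summary}


def report(table: pd.DataFrame, partner_conc_M: float | None = None) -> str:
    """Human-readable per-condition summary of a results table."""
    lines = []
    for cond, sub in table.groupby("condition", sort=True):
        lines.append(f"condition: {cond}")
        for _, row in sub.iterrows():
            if row.parameter == "t_TC_upper_bound":
                lines.append(
                    f"  t_TC upper bound (no peak above +3): "
                    f"{row.estimate * 1e6:.3g} us"
                )
            elif row.parameter == "t_TC" and np.isfinite(row.estimate):
                err = f" +/- {row.stderr * 1e6:.2g}" if np.isfinite(row.stderr) else ""
                lines.append(f"  t_TC = {row.estimate * 1e6:.3g}{err} us ({row.flags})")
            elif row.parameter == "k_A":
                lines.append(f"  k_A = {row.estimate:.3g} M^-1 s^-1")
            else:
                err = f" +/- {row.stderr:.3g}" if np.isfinite(row.stderr) else ""
                lines.append(f"  {row.parameter} = {row.estimate:.4g}{err}")
        if partner_conc_M is None and "k_A" not in set(sub.parameter):
            lines.append("  k_A omitted: no partner concentration supplied")
    return "\n".join(lines) + "\n"


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
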